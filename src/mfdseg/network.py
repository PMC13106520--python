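"""Model assembly, profiling and whole-model re-parameterization.

A model is described by a YAML stage list in the familiar one-row-per-module
dialect ``[from, repeats, module, args]``; the registry below maps module
names to the classes in :mod:`mfdseg.layers`.  The same description drives
construction, the forward pass, analytic parameter counting and FLOP
profiling, so every architecture variant (baseline / MFE-only / SD-only /
full model) is auditable from its config file alone.

FLOP convention: one multiply-accumulate counts as two floating-point
operations (the reporting convention of the single-stage detector family);
only convolutions (incl. transposed) are counted — normalization,
activations and resampling are omitted, which changes totals by well under
one percent.
"""

from __future__ import annotations

import copy
from importlib import resources

import numpy as np
import yaml

from . import layers, nn
from .errors import ConfigError, ModeError

_REGISTRY = {
    "Silence": layers.Silence,
    "Conv": layers.Conv,
    "RepNCSPELAN4": layers.RepNCSPELAN4,
    "ADown": layers.ADown,
    "SPPELAN": layers.SPPELAN,
    "Upsample": layers.Upsample,
    "Concat": layers.Concat,
    "CBLinear": layers.CBLinear,
    "CBFuse": layers.CBFuse,
    "SDDown": layers.SDDown,
    "ASFF3": layers.ASFF3,
    "Segment": layers.Segment,
    "DualDSegment": layers.DualDSegment,
}

_HEADS = ("Segment", "DualDSegment")


def load_config(name_or_path) -> dict:
    """Load a model config: a bundled name (e.g. ``'baseline'``) or a path."""
    text = None
    p = str(name_or_path)
    if p.endswith((".yaml", ".yml")):
        with open(p) as fh:
            text = fh.read()
    else:
        ref = resources.files("mfdseg.zoo").joinpath(f"{p}.yaml")
        text = ref.read_text()
    cfg = yaml.safe_load(text)
    if "stages" not in cfg:
        raise ConfigError("model config must define a 'stages' list")
    return cfg


class Model(nn.Module):
    """A stage-graph network built from a config dictionary."""

    def __init__(self, cfg: dict, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cfg = copy.deepcopy(cfg)
        self.nc = int(cfg.get("nc", 1))
        self.deployed = False
        rows = cfg["stages"]
        ch: list = []  # ch[i] = output channels of stage i (image has 3)
        self.layers_list: list[nn.Module] = []
        self.froms: list = []
        head_idx = None
        for li, row in enumerate(rows):
            frm, n, name, args = row
            if name not in _REGISTRY:
                raise ConfigError(f"unknown module {name!r} in stage {li}")
            cls = _REGISTRY[name]
            srcs = frm if isinstance(frm, list) else [frm]
            abs_srcs = [s if s >= 0 else li + s for s in srcs]
            in_ch = [3 if s < 0 else ch[s] for s in abs_srcs]
            mod, out_ch = self._build(cls, name, args, in_ch, n, rng)
            self.layers_list.append(mod)
            self.froms.append(abs_srcs if isinstance(frm, list) else abs_srcs[0])
            ch.append(out_ch)
            if name in _HEADS:
                head_idx = li
        if head_idx is None:
            raise ConfigError("config has no head stage")
        if head_idx != len(rows) - 1:
            raise ConfigError("the head must be the final stage")
        self._head_idx = head_idx
        self.channels = ch

    @property
    def head(self):
        return self.layers_list[self._head_idx]

    @staticmethod
    def _build(cls, name, args, in_ch, n, rng):
        c1 = in_ch[0]
        if name == "Conv":
            c2, k, s = (args + [1, 1])[:3]
            return cls(c1, c2, k, s, rng=rng), c2
        if name == "RepNCSPELAN4":
            c2, c3, c4 = args[:3]
            nrep = args[3] if len(args) > 3 else 1
            mfe = args[4] if len(args) > 4 else "none"
            alpha = float(args[5]) if len(args) > 5 else 1.0
            return cls(c1, c2, c3, c4, nrep, rng=rng, mfe=mfe, mfe_alpha=alpha), c2
        if name == "ADown":
            return cls(c1, args[0], rng=rng), args[0]
        if name == "SPPELAN":
            c2, c3 = args
            return cls(c1, c2, c3, rng=rng), c2
        if name == "Upsample":
            scale = args[0] if args else 2
            return cls(scale), c1
        if name == "Concat":
            return cls(), sum(in_ch)
        if name == "CBLinear":
            return cls(c1, args[0], rng=rng), list(args[0])
        if name == "CBFuse":
            return cls(args[0]), in_ch[-1]
        if name == "SDDown":
            c2 = args[0]
            k = args[1] if len(args) > 1 else 3
            s = args[2] if len(args) > 2 else 2
            return cls(c1, c2, k, s, rng=rng), c2
        if name == "ASFF3":
            target = args[0]
            wch = args[1] if len(args) > 1 else 8
            expand = args[2] if len(args) > 2 else "none"
            return cls(in_ch, target, wch, expand, rng=rng), in_ch[target]
        if name == "Silence":
            return cls(), c1
        if name in _HEADS:
            nc, nm, npr = args
            return cls(nc, nm, npr, in_ch, rng=rng), 0
        raise ConfigError(name)

    def forward(self, x, keep: set[int] | None = None):
        """Run the stage graph.  ``keep`` collects extra layer outputs
        (by index) into the returned dict under ``'feats'``."""
        if not isinstance(x, nn.Tensor):
            x = nn.Tensor(x)
        outputs: list = []
        feats: dict[int, object] = {}
        for li, (mod, frm) in enumerate(zip(self.layers_list, self.froms)):
            if isinstance(frm, list):
                y = mod([x if s < 0 else outputs[s] for s in frm])
            else:
                y = mod(x if frm < 0 else outputs[frm])
            outputs.append(y)
            if keep and li in keep:
                feats[li] = y
        if keep:
            y = dict(y)
            y["feats"] = feats
        return y


def build_model(config, rng: np.random.Generator | None = None) -> Model:
    """Build a model from a config name, path, or dictionary."""
    if isinstance(config, dict):
        return Model(config, rng)
    return Model(load_config(config), rng)


def reparameterize_model(model: Model) -> Model:
    """Replace every MFE block by its fused single convolution (in a copy).

    All other layers are untouched; a model without MFE blocks comes back
    with an identical parameter count.  Fusion uses the inference (running)
    batch-norm statistics.
    """
    if model.deployed:
        raise ModeError("model is already re-parameterized")
    out = copy.deepcopy(model)
    _fuse_in_place(out)
    out.deployed = True
    out.eval()
    return out


def _fuse_in_place(root: nn.Module):
    for mod in root.modules():
        for name, v in list(mod.__dict__.items()):
            if isinstance(v, layers.MFEConv):
                setattr(mod, name, v.fuse())
            elif isinstance(v, (list, tuple)):
                new = [m.fuse() if isinstance(m, layers.MFEConv) else m for m in v]
                if any(n is not o for n, o in zip(new, v)):
                    setattr(mod, name, type(v)(new) if isinstance(v, tuple) else new)


def count_params(model: Model) -> float:
    """Trainable parameters in millions, rounded to two decimals."""
    return round(model.num_params() / 1e6, 2)


def count_flops(model: Model, image_size: int = 640) -> float:
    """GFLOPs of one forward at ``image_size`` (2 x multiply-accumulates).

    The model is profiled at a reduced resolution and convolution costs are
    rescaled: every feature map's spatial extent scales with the square of
    the input side as long as all strides divide, so the rescaling is exact.
    """
    probe = 64
    if image_size % 32:
        raise ConfigError("image size must be a multiple of 32")
    was_training = model.training
    model.eval()
    nn.PROFILE = []
    try:
        with nn.no_grad():
            model.forward(np.zeros((1, 3, probe, probe), dtype=np.float32))
        macs = sum(nn.PROFILE)
    finally:
        nn.PROFILE = None
        model.train(was_training)
    return round(2.0 * macs * (image_size / probe) ** 2 / 1e9, 1)


def save_checkpoint(model: Model, path) -> None:
    """Serialize parameters + running stats + config + mode flag (.npz)."""
    import json

    arrays = model.state_dict()
    arrays["__config__"] = np.frombuffer(
        json.dumps(model.cfg).encode(), dtype=np.uint8
    )
    arrays["__deployed__"] = np.array([int(model.deployed)])
    np.savez(path, **arrays)


def load_checkpoint(path) -> Model:
    """Rebuild a model from a checkpoint written by :func:`save_checkpoint`."""
    import json

    with np.load(path) as z:
        cfg = json.loads(bytes(z["__config__"].tobytes()).decode())
        deployed = bool(z["__deployed__"][0])
        arrays = {k: z[k] for k in z.files if not k.startswith("__")}
    model = Model(cfg, np.random.default_rng(0))
    if deployed:
        model = reparameterize_model(model)
    model.load_state_dict(arrays)
    return model


def lead_p3_index(model: Model) -> int:
    """Layer index feeding the head's finest (lead P3) scale."""
    frm = model.froms[model._head_idx]
    nl = getattr(model.head, "nl", len(frm))
    return frm[nl] if len(frm) > nl else frm[0]


def feature_strides(model: Model, probe: int = 64) -> list[int]:
    """Downsampling factor of each head scale, measured by a probe forward."""
    model.eval()
    with nn.no_grad():
        out = model.forward(np.zeros((1, 3, probe, probe), dtype=np.float32))
    return [probe // s[1].shape[2] for s in out["scales"]]
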