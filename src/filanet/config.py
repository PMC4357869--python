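"""Flat key=value run configuration.

Every extraction and phantom parameter has a documented default; unknown
keys are rejected and a parsed config round-trips to an identical
document (keys are kept in canonical order).
"""

from __future__ import annotations

from dataclasses import fields

from filanet.dynamics import ExtractionParams
from filanet.phantom import PhantomSpec

_EXTRACTION_KEYS = {f.name for f in fields(ExtractionParams)}
_PHANTOM_KEYS = {f.name for f in fields(PhantomSpec)}

DEFAULTS: dict[str, object] = {}
for f in fields(ExtractionParams):
    DEFAULTS[f.name] = f.default
for f in fields(PhantomSpec):
    if f.name not in DEFAULTS:
        DEFAULTS[f.name] = f.default
DEFAULTS.update(
    spacing_x=1.0, spacing_y=1.0, spacing_z=1.0,
    background_offset=0.0,
    tau_min=0.006, tau_max=2.0, tau_steps=8,
    kstr_min=0.1, kstr_max=2.0, kstr_steps=8,
    tc_step=0.2,
)
# dataclass defaults that are factories/None need literal forms
DEFAULTS["bg_radii"] = "3,6"
DEFAULTS["intensity_range"] = "0,1"
DEFAULTS["psf_sigma"] = "1.73,1.73,5.0"
DEFAULTS["init_axes"] = "xyz"
DEFAULTS["damp_z"] = False


def _parse_value(key: str, raw: str):
    default = DEFAULTS[key]
    if isinstance(default, bool):
        if raw.lower() in ("1", "true", "yes", "on"):
            return True
        if raw.lower() in ("0", "false", "no", "off"):
            return False
        raise ValueError(f"{key}: expected a boolean, got {raw!r}")
    if isinstance(default, int) and not isinstance(default, bool):
        return int(raw)
    if isinstance(default, float):
        return float(raw)
    return raw


def parse_config(text: str) -> dict:
    """Parse ``key = value`` lines (``#`` comments allowed)."""
    cfg = dict(DEFAULTS)
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected 'key = value'")
        key, raw = (part.strip() for part in line.split("=", 1))
        if key not in DEFAULTS:
            raise ValueError(f"line {lineno}: unknown key {key!r}")
        cfg[key] = _parse_value(key, raw)
    return cfg


def format_config(cfg: dict) -> str:
    lines = [f"{key} = {cfg[key]}" for key in sorted(DEFAULTS)]
    return "\n".join(lines) + "\n"


def _tuple(raw, n, cast=float):
    parts = [cast(x) for x in str(raw).replace(",", " ").split()]
    if len(parts) != n:
        raise ValueError(f"expected {n} comma-separated values, got {raw!r}")
    return tuple(parts)


def extraction_params(cfg: dict) -> ExtractionParams:
    kwargs = {}
    for f in fields(ExtractionParams):
        if f.name not in cfg:
            continue
        val = cfg[f.name]
        if f.name == "bg_radii":
            val = _tuple(val, 2)
        elif f.name == "intensity_range":
            val = _tuple(val, 2)
        elif f.name == "init_axes":
            val = frozenset(str(val)) if val else None
        kwargs[f.name] = val
    return ExtractionParams(**kwargs)


def phantom_spec(cfg: dict) -> PhantomSpec:
    kwargs = {}
    for f in fields(PhantomSpec):
        if f.name not in cfg:
            continue
        val = cfg[f.name]
        if f.name == "psf_sigma":
            val = _tuple(val, 3)
        kwargs[f.name] = val
    return PhantomSpec(**kwargs)
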