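"""Registry of the 30 areal surface-texture parameters (ISO 25178-2).

The parameter set mirrors the standard DMTA reporting battery, organised in
five groups: height, functional (material-ratio / volume), spatial, hybrid
and feature (watershed-segmentation) parameters.  Units follow the ISO
definitions; all lengths are in µm internally.
"""

from __future__ import annotations

from dataclasses import dataclass

HEIGHT_PARAMS = ("Sp", "Ssk", "Sku", "Sq", "Sv", "Sz", "Sa")
FUNCTIONAL_PARAMS = ("Smr", "Smc", "Sxp", "Vm", "Vv", "Vmp", "Vmc", "Vvc", "Vvv")
SPATIAL_PARAMS = ("Sal", "Str", "Std")
HYBRID_PARAMS = ("Sdq", "Sdr")
FEATURE_PARAMS = ("Spd", "Spc", "S10z", "S5p", "S5v", "Sda", "Sha", "Sdv", "Shv")

PARAMETER_GROUPS = {
    "height": HEIGHT_PARAMS,
    "functional": FUNCTIONAL_PARAMS,
    "spatial": SPATIAL_PARAMS,
    "hybrid": HYBRID_PARAMS,
    "feature": FEATURE_PARAMS,
}

#: Canonical column order for measurement tables.
ALL_PARAMS: tuple[str, ...] = (
    HEIGHT_PARAMS + FUNCTIONAL_PARAMS + SPATIAL_PARAMS + HYBRID_PARAMS + FEATURE_PARAMS
)


@dataclass(frozen=True)
class ParamInfo:
    name: str
    group: str
    unit: str
    description: str


_UNITS = {
    "Sq": ("µm", "root-mean-square height"),
    "Ssk": ("-", "skewness of the height distribution"),
    "Sku": ("-", "kurtosis of the height distribution"),
    "Sp": ("µm", "maximum peak height"),
    "Sv": ("µm", "maximum pit depth"),
    "Sz": ("µm", "maximum height (Sp + Sv)"),
    "Sa": ("µm", "arithmetical mean height"),
    "Smr": ("%", "areal material ratio at the reference height"),
    "Smc": ("µm", "inverse areal material ratio (p = 10%)"),
    "Sxp": ("µm", "peak extreme height, c(p) - c(q) with p = 50%, q = 97.5%"),
    "Vm": ("µm³/µm²", "material volume at p = 10%"),
    "Vv": ("µm³/µm²", "void volume at p = 10%"),
    "Vmp": ("µm³/µm²", "peak material volume (p = 10%)"),
    "Vmc": ("µm³/µm²", "core material volume (p = 10%, q = 80%)"),
    "Vvc": ("µm³/µm²", "core void volume (p = 10%, q = 80%)"),
    "Vvv": ("µm³/µm²", "valley void volume (p = 80%)"),
    "Sal": ("µm", "autocorrelation length (s = 0.2)"),
    "Str": ("-", "texture aspect ratio (s = 0.2)"),
    "Std": ("°", "texture (lay) direction, counter-clockwise from +x"),
    "Sdq": ("-", "root-mean-square surface gradient"),
    "Sdr": ("%", "developed interfacial area ratio"),
    "Spd": ("1/µm²", "density of significant peaks (pruning = 5%)"),
    "Spc": ("1/µm", "arithmetic mean peak curvature (pruning = 5%)"),
    "S10z": ("µm", "ten-point height, S5p + S5v (pruning = 5%)"),
    "S5p": ("µm", "five-point peak height (pruning = 5%)"),
    "S5v": ("µm", "five-point pit depth (pruning = 5%)"),
    "Sda": ("µm²", "mean closed dale area (pruning = 5%)"),
    "Sha": ("µm²", "mean closed hill area (pruning = 5%)"),
    "Sdv": ("µm³", "mean closed dale volume (pruning = 5%)"),
    "Shv": ("µm³", "mean closed hill volume (pruning = 5%)"),
}

REGISTRY: dict[str, ParamInfo] = {
    name: ParamInfo(name, group, _UNITS[name][0], _UNITS[name][1])
    for group, names in PARAMETER_GROUPS.items()
    for name in names
}

assert len(ALL_PARAMS) == 30


def validate_param_names(names) -> None:
    """Raise if ``names`` is not exactly the 30-parameter registry."""
    from .errors import SchemaError

    names = list(names)
    unknown = sorted(set(names) - set(ALL_PARAMS))
    missing = sorted(set(ALL_PARAMS) - set(names))
    if unknown:
        raise SchemaError(f"unknown parameter columns: {unknown}")
    if missing:
        raise SchemaError(f"missing parameter columns: {missing}")
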