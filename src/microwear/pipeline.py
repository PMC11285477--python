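"""End-to-end study orchestration: measure scans, compare groups, simulate.

``measure`` turns a set of scans into a measurement table (one row per scan
with all 30 parameters), ``compare`` runs the robust three-test battery on
the requested factors/subsets, and ``simulate_and_run`` chains the synthetic
study generator into both, writing a reproducibility manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .errors import DesignError
from .feature_params import feature_parameters, segment
from .field_params import (
    ParamSettings,
    bearing_curve,
    functional_params,
    height_params,
    hybrid_params,
    spatial_params,
)
from .preprocess import PreprocessSettings, sf_surface
from .registry import ALL_PARAMS
from .robust_stats import StatsConfig, compare_parameters
from .surface_io import (
    META_COLUMNS,
    HeightMap,
    MeasurementTable,
    fill_nonmeasured,
    read_csv_grid,
    read_sdf,
    write_table,
)
from .synthetic import StudyDesign, gen_study

log = logging.getLogger("microwear")

#: the study's standard comparisons: (label, factor, subset filters)
STANDARD_COMPARISONS = (
    ("population (P4 facet 9)", "population", {"tooth": "P4", "facet": "9"}),
    ("sex (facets 3 and 9)", "sex", {"facet": ["3", "9"]}),
    ("tooth row (P4-9 vs M1-3)", "tooth", {"tooth": ["P4", "M1"]}),
    ("tooth jaw (M1-3 vs m2-9)", "tooth", {"tooth": ["M1", "m2"]}),
)


@dataclass
class PipelineConfig:
    preprocess: PreprocessSettings = field(default_factory=PreprocessSettings)
    parameters: ParamSettings = field(default_factory=ParamSettings)
    stats: StatsConfig = field(default_factory=StatsConfig)
    prune_fraction: float = 0.05
    comparisons: tuple = STANDARD_COMPARISONS
    seed: int = 0


def measure_scan(hm: HeightMap, config: PipelineConfig | None = None) -> tuple[dict, set]:
    """All 30 parameters of one scan, computed on its S-F surface."""
    config = config or PipelineConfig()
    sf = sf_surface(hm, config.preprocess)
    filled = fill_nonmeasured(sf)
    params: dict[str, float] = {}
    flags: set[str] = set()
    for p, f in (
        height_params(sf),
        functional_params(sf, bearing_curve(sf), config.parameters),
        spatial_params(filled, config.parameters),
        hybrid_params(filled),
    ):
        params.update(p)
        flags |= f
    seg = segment(filled, config.prune_fraction)
    p, f = feature_parameters(seg)
    params.update(p)
    flags |= f
    return params, flags


def measure(scans, config: PipelineConfig | None = None) -> MeasurementTable:
    """Measure an iterable of HeightMaps (or paths) into a MeasurementTable.

    Scan metadata (specimen, population, ...) is taken from each map's
    ``meta``; unreadable scans are skipped with a logged warning.
    """
    config = config or PipelineConfig()
    rows = []
    failures = 0
    for item in scans:
        try:
            hm = _as_heightmap(item)
            params, flags = measure_scan(hm, config)
        except Exception as exc:  # degraded input: skip, keep going
            failures += 1
            log.warning("skipping scan %s: %s", getattr(item, "meta", item), exc)
            continue
        row = {c: str(hm.meta.get(c, "unknown")) for c in META_COLUMNS}
        row.update(params)
        row["flags"] = ";".join(sorted(flags))
        rows.append(row)
    if not rows:
        raise DesignError(f"all {failures} scans failed to measure")
    df = pd.DataFrame(rows, columns=list(META_COLUMNS) + list(ALL_PARAMS) + ["flags"])
    return MeasurementTable(df)


def _as_heightmap(item) -> HeightMap:
    if isinstance(item, HeightMap):
        return item
    path = Path(item)
    if path.suffix.lower() == ".sdf":
        return read_sdf(path)
    if path.suffix.lower() == ".csv":
        return read_csv_grid(path, dx=1.0, dy=1.0)
    raise ValueError(f"unrecognised scan format: {path}")


def compare(table: MeasurementTable, config: PipelineConfig | None = None) -> dict:
    """Run each configured comparison; returns {label: result DataFrame}.

    Subset filters are applied before grouping, so excluded rows never enter
    any statistic.  Comparisons whose subset lacks two factor levels raise
    :class:`DesignError` naming the filter.
    """
    config = config or PipelineConfig()
    out = {}
    for label, factor, filters in config.comparisons:
        sub = table.subset(**filters) if filters else table
        if len(sub) == 0:
            raise DesignError(f"comparison {label!r}: empty subset after filters {filters}")
        res = compare_parameters(sub, factor, config.stats, label=label)
        out[label] = res
    return out


def summarize(results: dict) -> pd.DataFrame:
    """Per-comparison counts of flagged parameters."""
    rows = [
        {"comparison": label, "n_rows": len(df), "n_significant": int(df["significant"].sum()),
         "significant": ",".join(sorted(df.loc[df["significant"], "parameter"].unique()))}
        for label, df in results.items()
    ]
    return pd.DataFrame(rows)


def simulate_and_run(design: StudyDesign, config: PipelineConfig | None = None, outdir=None) -> dict:
    """gen_study → measure → compare, with a provenance manifest.

    Returns {"table", "truth", "results", "summary", "manifest"}; when
    ``outdir`` is given, writes measurement CSV, per-comparison CSVs, the
    truth table and the JSON manifest there.
    """
    config = config or PipelineConfig()
    maps, truth = gen_study(design)
    table = measure(maps, config)
    # only compare factors that vary in this design
    comparisons = []
    for label, factor, filters in config.comparisons:
        try:
            sub = table.subset(**filters) if filters else table
        except Exception:
            continue
        if sub.data[factor].nunique() >= 2:
            comparisons.append((label, factor, filters))
    run_config = PipelineConfig(
        preprocess=config.preprocess, parameters=config.parameters, stats=config.stats,
        prune_fraction=config.prune_fraction, comparisons=tuple(comparisons), seed=design.master_seed,
    )
    results = compare(table, run_config)
    summary = summarize(results)
    manifest = {
        "seed": design.master_seed,
        "version": __version__,
        "n_scans": len(maps),
        "scan_shape": list(design.shape),
        "comparisons": [c[0] for c in comparisons],
        "config_hash": hashlib.sha256(
            repr((design, run_config)).encode()
        ).hexdigest()[:16],
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_table(table, outdir / "measurements.csv")
        truth.to_csv(outdir / "truth.csv", index=False, float_format="%.10g")
        for label, df in results.items():
            safe = "".join(ch if ch.isalnum() else "_" for ch in label)
            df.to_csv(outdir / f"comparison_{safe}.csv", index=False, float_format="%.10g")
        summary.to_csv(outdir / "summary.csv", index=False)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"table": table, "truth": truth, "results": results, "summary": summary,
            "manifest": manifest}
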