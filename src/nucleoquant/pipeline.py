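"""Batch orchestration and group statistics.

A batch run is driven by a manifest CSV (columns ``id``, ``group`` and the
path columns the analysis needs), an :class:`AnalysisConfig` naming the
analysis kind and its options, and a seed.  Outputs are deterministic for a
fixed (config, seed): a tidy per-record CSV, a summary JSON and a plain-text
log.  Per-record failures are logged and skipped, never abort the batch.

Group comparisons mirror the reporting conventions of condensate imaging
studies: two groups are compared with the two-sided Wilcoxon rank-sum test;
three or more with one-way ANOVA followed by Tukey HSD pairwise comparisons
(the omnibus F is always reported alongside the Tukey pairs).
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from . import __version__
from .colocalization import channel_correlation, relative_positional_variance, signal_center
from .errors import InsufficientDataError, NucleoQuantError
from .frap import FrapExperiment, normalize_with_correction
from .image_io import read_stack
from .morphometry import (
    compute_signal_metrics,
    flag_outliers,
    volume_intensity_correlation,
)
from .segmentation import filter_stack
from .texture import homogeneity_score

ANALYSIS_KINDS = ("homogeneity", "volint", "heterogeneity", "coloc", "rpv", "frap")

#: Option defaults, echoed into every summary so reports are self-describing.
DEFAULT_OPTIONS = {
    "projection_mode": "sum",
    "sd_convention": "population",
    "outlier_n_mad": 3.0,
    "support_rule": "union",
    "rpv_units": "um",
    "center_weighted": True,
    "bleach_reference": "signal",
}


@dataclass
class AnalysisConfig:
    kind: str
    manifest: Path
    out_dir: Path
    options: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ANALYSIS_KINDS:
            raise ValueError(f"unknown analysis kind {self.kind!r}")
        self.manifest = Path(self.manifest)
        self.out_dir = Path(self.out_dir)
        merged = dict(DEFAULT_OPTIONS)
        merged.update(self.options)
        self.options = merged

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        return cls(**data)


@dataclass
class BatchResult:
    table: pd.DataFrame
    summary: dict
    failures: list[tuple[str, str]]

    @property
    def fully_succeeded(self) -> bool:
        return not self.failures


def run_batch(config: AnalysisConfig) -> BatchResult:
    """Run one analysis over every manifest row; write CSV, JSON and log."""
    manifest = pd.read_csv(config.manifest)
    if manifest.empty:
        raise InsufficientDataError(f"manifest {config.manifest} has no rows")
    handler = _HANDLERS[config.kind]
    config.out_dir.mkdir(parents=True, exist_ok=True)

    rows: list[dict] = []
    failures: list[tuple[str, str]] = []
    timings: list[str] = []
    for record in manifest.to_dict(orient="records"):
        rec_id = str(record.get("id", ""))
        t0 = time.perf_counter()
        try:
            row = handler(record, config.options)
        except (NucleoQuantError, OSError, ValueError) as exc:
            failures.append((rec_id, f"{type(exc).__name__}: {exc}"))
            timings.append(f"{rec_id}\tFAILED\t{time.perf_counter() - t0:.3f}s")
            continue
        row = {"id": rec_id, "group": record.get("group", ""), **row}
        rows.append(row)
        timings.append(f"{rec_id}\tok\t{time.perf_counter() - t0:.3f}s")

    table = pd.DataFrame(rows)
    summary = {
        "kind": config.kind,
        "seed": config.seed,
        "options": config.options,
        "n_records": len(rows),
        "n_failures": len(failures),
    }
    summary.update(_summarize(config.kind, table, config.options))

    table.to_csv(config.out_dir / "records.csv", index=False, float_format="%.10g")
    with open(config.out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_jsonable)
    with open(config.out_dir / "run.log", "w") as fh:
        fh.write(f"nucleoquant {__version__}\n")
        fh.write(f"kind: {config.kind}\nmanifest: {config.manifest}\n")
        fh.write(f"seed: {config.seed}\noptions: {json.dumps(config.options, sort_keys=True)}\n")
        fh.write("\n".join(timings) + "\n")
        for rec_id, msg in failures:
            fh.write(f"FAILURE\t{rec_id}\t{msg}\n")
    return BatchResult(table=table, summary=summary, failures=failures)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# per-record handlers


def _handle_homogeneity(record: dict, options: dict) -> dict:
    stack = read_stack(record["path_channel1"])
    res = homogeneity_score(stack, projection_mode=options["projection_mode"])
    return {
        "file": record["path_channel1"],
        "threshold": res.threshold_used,
        "n_pairs": res.n_pairs,
        "homogeneity": res.score,
    }


def _metrics_row(record: dict, options: dict) -> dict:
    stack = read_stack(record["path_channel1"])
    m = compute_signal_metrics(stack, sd_convention=options["sd_convention"])
    row = {"file": record["path_channel1"]}
    row.update(dataclasses.asdict(m))
    return row


def _handle_coloc(record: dict, options: dict) -> dict:
    a = filter_stack(read_stack(record["path_channel1"]))
    b = filter_stack(read_stack(record["path_channel2"]))
    corr = channel_correlation(a, b, support=options["support_rule"])
    return {
        "file_channel1": record["path_channel1"],
        "file_channel2": record["path_channel2"],
        "pearson_r": corr.pearson_r,
        "p_value": corr.p_value,
        "n_voxels": corr.n_voxels,
        "support_rule": corr.support_rule,
    }


def _handle_rpv(record: dict, options: dict) -> dict:
    a = filter_stack(read_stack(record["path_channel1"]))
    b = filter_stack(read_stack(record["path_channel2"]))
    corr = channel_correlation(a, b, support=options["support_rule"])
    center = signal_center(b, weighted=options["center_weighted"])
    disp = relative_positional_variance(a, center, units=options["rpv_units"])
    return {
        "file_channel1": record["path_channel1"],
        "file_channel2": record["path_channel2"],
        "pearson_r": corr.pearson_r,
        "p_value": corr.p_value,
        "n_voxels": corr.n_voxels,
        "support_rule": corr.support_rule,
        "center_z": center[0],
        "center_y": center[1],
        "center_x": center[2],
        "mu": disp.mu,
        "sigma2": disp.sigma2,
        "rpv": disp.rpv,
        "rpv_units": disp.units,
    }


def _handle_frap(record: dict, options: dict) -> dict:
    exp = FrapExperiment(
        prebleach=read_stack(record["prebleach"]).intensities,
        laser=read_stack(record["laser"]).intensities,
        timelapse=read_stack(record["timelapse"], is_timelapse=True).intensities,
    )
    curve = normalize_with_correction(exp, reference=options["bleach_reference"])
    return {
        "prebleach": record["prebleach"],
        "percent_recovery": curve.percent_recovery,
        "unrecovered_fraction": curve.unrecovered_fraction,
        "bleach_rate": curve.bleach_rate,
        "rate_adjusted": curve.rate_adjusted,
        "prebleach_mean": curve.prebleach_mean,
    }


_HANDLERS = {
    "homogeneity": _handle_homogeneity,
    "volint": _metrics_row,
    "heterogeneity": _metrics_row,
    "coloc": _handle_coloc,
    "rpv": _handle_rpv,
    "frap": _handle_frap,
}


def _summarize(kind: str, table: pd.DataFrame, options: dict) -> dict:
    """Population summaries per analysis kind (per group where grouped)."""
    if table.empty:
        return {}
    out: dict = {}
    if kind == "volint":
        per_group = {}
        for name, sub in table.groupby("group", sort=True):
            try:
                from .morphometry import SignalMetrics

                records = [
                    SignalMetrics(
                        volume=int(r.volume),
                        mean_above_bg=float(r.mean_above_bg),
                        compression=float(r.compression),
                        heterogeneity=float(r.heterogeneity),
                        integrated_intensity=float(r.integrated_intensity),
                        in_focus_area=int(r.in_focus_area),
                        max_proj_area=int(r.max_proj_area),
                        sum_proj_area=int(r.sum_proj_area),
                        threshold=float(r.threshold),
                    )
                    for r in sub.itertuples()
                ]
                res = volume_intensity_correlation(records)
                per_group[str(name)] = dataclasses.asdict(res)
            except NucleoQuantError as exc:
                per_group[str(name)] = {"error": str(exc)}
        out["volume_intensity_correlation"] = per_group
    return out


# ---------------------------------------------------------------------------
# group statistics


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns (W, p) where W is the rank sum of the first sample.  Exact null
    distribution for small tie-free samples, normal approximation (with tie
    correction) otherwise.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    w = float(res.statistic) + len(x) * (len(x) + 1) / 2.0
    return w, float(res.pvalue)


def compare_groups(groups: dict[str, np.ndarray], test: str = "auto") -> pd.DataFrame:
    """Pairwise group comparisons as reported in figure legends.

    ``test``: ``"ranksum"`` (two groups), ``"anova_tukey"`` (>= 2 groups), or
    ``"auto"`` (rank-sum for two groups, ANOVA + Tukey otherwise).  Returns a
    tidy frame with one row per comparison; for ANOVA the omnibus F-test is
    included as an extra row with comparison label ``"omnibus"``.
    """
    names = sorted(groups)
    if len(names) < 2:
        raise InsufficientDataError("need >= 2 groups")
    for name in names:
        if len(np.atleast_1d(groups[name])) < 3:
            raise InsufficientDataError(f"group {name!r} has < 3 records")
    if test == "auto":
        test = "ranksum" if len(names) == 2 else "anova_tukey"

    rows = []
    if test == "ranksum":
        if len(names) != 2:
            raise ValueError("rank-sum test compares exactly 2 groups")
        w, p = rank_sum_test(groups[names[0]], groups[names[1]])
        rows.append(
            {"group1": names[0], "group2": names[1], "test": "ranksum",
             "statistic": w, "p_value": p}
        )
    elif test == "anova_tukey":
        samples = [np.asarray(groups[n], dtype=np.float64) for n in names]
        f_stat, f_p = stats.f_oneway(*samples)
        rows.append(
            {"group1": "omnibus", "group2": "", "test": "anova_F",
             "statistic": float(f_stat), "p_value": float(f_p)}
        )
        values = np.concatenate(samples)
        labels = np.concatenate([[n] * len(s) for n, s in zip(names, samples)])
        tukey = pairwise_tukeyhsd(values, labels)
        pair_idx = list(zip(*tukey._multicomp.pairindices))
        for (i, j), diff, p_adj in zip(pair_idx, tukey.meandiffs, tukey.pvalues):
            g1, g2 = tukey.groupsunique[i], tukey.groupsunique[j]
            rows.append(
                {"group1": str(g1), "group2": str(g2), "test": "tukey_hsd",
                 "statistic": float(diff), "p_value": float(p_adj)}
            )
    else:
        raise ValueError(f"unknown test {test!r}")
    return pd.DataFrame(rows)
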