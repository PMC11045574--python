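"""End-to-end Mokken analysis: scalability, AISP sweep, monotonicity,
invariant item ordering, level-sum scoring and known-group comparisons,
pooled and stratified, with a machine-readable report bundle.

Every output table is written as CSV and indexed in one JSON manifest that
echoes the full configuration and seed; rerunning from the manifest's
config reproduces the bundle bit for bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .aisp import find_split_threshold, prepare_pair_stats, sweep_lower_bounds
from .data_model import GroupLabels, ResponseMatrix, ScaleDefinition, complete_cases
from .errors import EmptyDataError, ScalemokError
from .iio import check_miio
from .monotonicity import check_monotonicity, irf_table
from .scalability import compute_H
from .scoring import compute_lss, cronbach_alpha, guttman_lambda2

logger = logging.getLogger("scalemok")

__all__ = ["AnalysisConfig", "run_full_analysis", "rank_sum_test", "spearman_correlation"]


def rank_sum_test(scores_a, scores_b) -> tuple[float, float]:
    """Wilcoxon/Mann-Whitney rank-sum test with mid-rank ties.

    Normal approximation with tie correction, two-sided; returns
    ``(U_a, p)`` where U_a is the U statistic of the first group.  When
    both groups hold the same multiset of values p = 1.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ScalemokError("both groups must be non-empty")
    if np.unique(np.concatenate([a, b])).size == 1:
        return float(a.size * b.size / 2.0), 1.0  # every value tied
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    return float(res.statistic), float(res.pvalue)


def spearman_correlation(scores, external) -> float:
    """Spearman rho with mid-rank ties; NaN when either vector is constant."""
    x = np.asarray(scores, dtype=float)
    y = np.asarray(external, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ScalemokError("need >= 3 paired observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


@dataclass
class AnalysisConfig:
    """Everything one full analysis run depends on, echoed into the manifest."""

    scales: dict[str, list[str]]  # name -> item ids; first entry = full scale
    bounds: list[float] = field(
        default_factory=lambda: [round(0.1 + 0.05 * k, 2) for k in range(11)]
    )
    minvi: float = 0.03
    minsize: int | None = None  # None -> standard sample-size ladder
    bootstrap_reps: int = 1000
    aisp_bootstrap_reps: int = 200
    alpha: float = 0.05
    split_step: float = 0.001
    strata: list[str] = field(default_factory=list)
    known_groups: list[str] = field(default_factory=list)
    stratum_floor: int = 500
    seed: int = 0
    outdir: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _analyze_subset(
    matrix: ResponseMatrix,
    labels: GroupLabels | None,
    config: AnalysisConfig,
    seeds: dict[str, int],
    tag: str,
) -> dict:
    """All scale-level analyses on one (sub)population."""
    out: dict = {"tag": tag, "n": matrix.n_respondents, "scales": {}}
    first = True
    for name, items in config.scales.items():
        scale = ScaleDefinition(name, items)
        try:
            data = complete_cases(matrix, scale)
        except EmptyDataError:
            logger.warning("%s/%s: no complete cases, skipped", tag, name)
            out["scales"][name] = {"skipped": "no complete cases"}
            continue
        entry: dict = {"n_complete": data.n_respondents}
        h = compute_H(
            data, bootstrap_reps=config.bootstrap_reps, seed=seeds["scalability"]
        )
        entry["scalability"] = h
        mono, isrf = check_monotonicity(
            data, minvi=config.minvi, minsize=config.minsize, alpha=config.alpha
        )
        entry["monotonicity"] = mono
        entry["isrf"] = isrf
        if len(items) >= 3:
            entry["iio"] = check_miio(data, minsize=config.minsize, alpha=config.alpha)
        entry["alpha"] = cronbach_alpha(data, ScaleDefinition(name, list(data.item_ids)))
        entry["lambda2"] = guttman_lambda2(data, ScaleDefinition(name, list(data.item_ids)))
        entry["lss"] = compute_lss(matrix, scale)
        if first:
            ps = prepare_pair_stats(
                data, bootstrap_reps=config.aisp_bootstrap_reps, seed=seeds["aisp"]
            )
            entry["aisp_sweep"] = sweep_lower_bounds(
                data, config.bounds, alpha=config.alpha,
                bootstrap_reps=config.aisp_bootstrap_reps, seed=seeds["aisp"],
            )
            entry["split_threshold"] = find_split_threshold(
                data, step=config.split_step, alpha=config.alpha, pair_stats=ps
            )
            first = False
        out["scales"][name] = entry
    return out


def _known_group_tests(
    matrix: ResponseMatrix, labels: GroupLabels, config: AnalysisConfig
) -> pd.DataFrame:
    """Median/IQR of the 0-100 LSS per group with rank-sum p-values."""
    rows = []
    for name, items in config.scales.items():
        scale = ScaleDefinition(name, items)
        lss = compute_lss(matrix, scale)
        scored = dict(zip(lss.respondent_index, lss.transformed))
        for var in config.known_groups:
            if var not in labels.labels:
                logger.warning("known-group variable %r missing, skipped", var)
                continue
            lab = np.asarray(labels.labels[var])
            values = {}
            for level in sorted(np.unique(lab)):
                rows_in = np.flatnonzero(lab == level)
                values[level] = np.array(
                    [scored[r] for r in rows_in if r in scored]
                )
            levels_present = [k for k, v in values.items() if v.size > 0]
            p = u = np.nan
            if len(levels_present) == 2:
                u, p = rank_sum_test(
                    values[levels_present[0]], values[levels_present[1]]
                )
            for level in levels_present:
                v = values[level]
                rows.append(
                    {
                        "scale": name,
                        "variable": var,
                        "group": level,
                        "n": v.size,
                        "median": float(np.median(v)),
                        "q1": float(np.percentile(v, 25)),
                        "q3": float(np.percentile(v, 75)),
                        "U": u,
                        "p_ranksum": p,
                    }
                )
    return pd.DataFrame(rows)


def _write_subset(entry: dict, outdir: Path, manifest_files: list) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for name, scale_entry in entry["scales"].items():
        if "skipped" in scale_entry:
            continue
        h = scale_entry["scalability"]
        df = h.to_frame()
        df["H_scale"] = h.H_scale
        df["label"] = h.label
        _save(df, outdir / f"scalability_{name}.csv", manifest_files)
        _save(scale_entry["monotonicity"].to_frame(), outdir / f"monotonicity_{name}.csv", manifest_files)
        _save(irf_table(scale_entry["isrf"]), outdir / f"irf_{name}.csv", manifest_files)
        if "iio" in scale_entry:
            iio = scale_entry["iio"]
            df = iio.to_frame()
            df["HT"] = iio.HT.value if iio.HT else np.nan
            df["HT_label"] = iio.HT.label if iio.HT else ""
            df["removed"] = [",".join(iio.removed_items)] * len(df)
            _save(df, outdir / f"iio_{name}.csv", manifest_files)
        if "aisp_sweep" in scale_entry:
            _save(
                scale_entry["aisp_sweep"].rename_axis("item").reset_index(),
                outdir / "aisp_sweep.csv",
                manifest_files,
            )


def _save(df: pd.DataFrame, path: Path, manifest_files: list) -> None:
    df.to_csv(path, index=False, float_format="%.10g")
    manifest_files.append(str(path))


def run_full_analysis(
    matrix: ResponseMatrix,
    labels: GroupLabels | None,
    config: AnalysisConfig,
) -> dict:
    """Run the whole analysis design; returns the report bundle.

    When ``config.outdir`` is set, writes every table as CSV plus a JSON
    manifest (config echo, seed, file list, skipped strata, summary
    statistics).  Strata below ``stratum_floor`` complete cases are
    skipped with a logged reason, not an error.
    """
    seq = np.random.SeedSequence(config.seed)
    seed_names = ("scalability", "aisp", "strata")
    seeds = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(seed_names, seq.spawn(len(seed_names)))
    }

    bundle: dict = {"config": config.to_dict(), "seeds": seeds}
    bundle["pooled"] = _analyze_subset(matrix, labels, config, seeds, "pooled")
    if labels is not None and config.known_groups:
        bundle["known_groups"] = _known_group_tests(matrix, labels, config)

    bundle["strata"] = {}
    skipped: list[dict] = []
    if labels is not None:
        for var in config.strata:
            if var not in labels.labels:
                skipped.append({"stratum": var, "reason": "variable missing"})
                continue
            lab = np.asarray(labels.labels[var])
            for level in sorted(np.unique(lab)):
                mask = lab == level
                n = int(mask.sum())
                key = f"{var}={level}"
                if n < config.stratum_floor:
                    skipped.append(
                        {"stratum": key, "n": n, "reason": "below stratum floor"}
                    )
                    logger.info("stratum %s skipped (n=%d)", key, n)
                    continue
                sub = matrix.select_rows(mask)
                bundle["strata"][key] = _analyze_subset(
                    sub, labels.subset(np.flatnonzero(mask)), config, seeds, key
                )
    bundle["skipped_strata"] = skipped

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        files: list = []
        _write_subset(bundle["pooled"], outdir, files)
        if "known_groups" in bundle:
            _save(bundle["known_groups"], outdir / "known_groups.csv", files)
        for key, entry in bundle["strata"].items():
            _write_subset(entry, outdir / "strata" / key.replace("/", "_"), files)
        # outdir is omitted from the echo so a relocated bundle stays
        # byte-identical to the original
        manifest = {
            "config": {k: v for k, v in config.to_dict().items() if k != "outdir"},
            "seeds": seeds,
            "files": sorted(str(Path(f).relative_to(outdir)) for f in files),
            "skipped_strata": skipped,
            "summary": _summary(bundle),
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        with open(outdir / "log.txt", "w") as fh:
            fh.write(f"seed: {config.seed}\n")
            for tag, entry in [("pooled", bundle["pooled"]), *bundle["strata"].items()]:
                for name, se in entry["scales"].items():
                    if "skipped" in se:
                        fh.write(f"{tag}/{name}: skipped ({se['skipped']})\n")
                        continue
                    h = se["scalability"]
                    excluded = entry["n"] - se["n_complete"]
                    fh.write(
                        f"{tag}/{name}: n={se['n_complete']} "
                        f"excluded={excluded} "
                        f"degenerate_items={','.join(h.excluded_items) or 'none'}\n"
                    )
            for s in skipped:
                fh.write(f"stratum skipped: {s}\n")
            fh.write("note: no multiple-testing correction applied\n")
    return bundle


def _summary(bundle: dict) -> dict:
    """Scalar highlights of the pooled run for the manifest."""
    out = {}
    for name, entry in bundle["pooled"]["scales"].items():
        if "skipped" in entry:
            continue
        h = entry["scalability"]
        out[name] = {
            "n": entry["n_complete"],
            "H_scale": float(h.H_scale),
            "label": h.label,
            "monotonicity_vi": int(entry["monotonicity"].vi.sum()),
            "alpha": float(entry["alpha"]),
            "lambda2": float(entry["lambda2"]),
        }
        if "iio" in entry and entry["iio"].HT is not None:
            out[name]["HT"] = float(entry["iio"].HT.value)
        if "split_threshold" in entry:
            t = entry["split_threshold"]
            out[name]["split_threshold"] = None if t is None else float(t)
    return out
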