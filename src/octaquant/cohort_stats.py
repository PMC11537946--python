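"""Cohort-level aggregation and TR-vs-GT statistical comparison.

Features are summarized per (group, arm, fov) as n / mean / sample SD, and
each feature is compared between the translated and ground-truth arms with a
two-tailed t-test.  Because "two-tailed t-test" underdetermines the recipe,
both readings are computed and reported: unpaired Welch (unequal variances,
Welch–Satterthwaite degrees of freedom; the default headline) and the paired
test, which is natural here since TR and GT are per-subject pairs.  No
multiple-testing correction is applied; the report records the number of
tests run so users can correct externally.

NaN feature values (sentinels from degenerate images) are excluded listwise
per feature, with exclusion counts reported.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["summarize", "ttest_tr_vs_gt", "build_report", "FEATURES"]

FEATURES = ("bvd", "bvc", "bvt", "vpi")
ALPHA = 0.05


def summarize(features: pd.DataFrame, feature_cols=FEATURES) -> pd.DataFrame:
    """Per-(group, arm, fov, feature) n, mean and sample SD (ddof=1).

    NaN values are dropped per feature with the count reported in
    ``n_excluded``.  A group/feature cell with a single retained value gets
    a null SD; an empty cell gets null mean and SD.  Row order of the input
    does not affect the output (sorted keys).
    """
    required = {"group", "arm", "fov"}
    missing = required - set(features.columns)
    if missing:
        raise ValueError(f"features table missing columns: {sorted(missing)}")
    rows = []
    for (group, arm, fov), sub in features.groupby(["group", "arm", "fov"], sort=True):
        for feat in feature_cols:
            vals = pd.to_numeric(sub[feat], errors="coerce")
            kept = vals.dropna()
            rows.append(
                {
                    "group": group,
                    "arm": arm,
                    "fov": fov,
                    "feature": feat,
                    "n": int(len(kept)),
                    "n_excluded": int(len(vals) - len(kept)),
                    "mean": float(kept.mean()) if len(kept) >= 1 else np.nan,
                    "sd": float(kept.std(ddof=1)) if len(kept) >= 2 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def ttest_tr_vs_gt(x_tr, x_gt, paired: bool = False) -> tuple[float, float]:
    """Two-tailed t-test between the TR and GT arm values of one feature.

    Unpaired mode is Welch's test (unequal variances assumed); paired mode
    tests the per-subject differences and requires equal lengths.  The
    degenerate zero-variance, equal-mean case (e.g. an identity
    degradation, where TR == GT exactly) returns t=0, p=1 rather than the
    undefined 0/0 statistic.
    """
    a = np.asarray(x_tr, dtype=float)
    b = np.asarray(x_gt, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError(f"each arm needs n >= 2, got {len(a)} and {len(b)}")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test needs equal-length arms")
        diffs = a - b
        if np.allclose(diffs.std(ddof=1), 0.0) and np.allclose(diffs.mean(), 0.0):
            return 0.0, 1.0
        res = stats.ttest_rel(a, b)
    else:
        if (
            np.allclose(a.std(ddof=1), 0.0)
            and np.allclose(b.std(ddof=1), 0.0)
            and np.allclose(a.mean(), b.mean())
        ):
            return 0.0, 1.0
        res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def _ttest_block(features: pd.DataFrame, feature_cols) -> list[dict]:
    out = []
    for fov, sub in features.groupby("fov", sort=True):
        tr = sub[sub["arm"] == "TR"]
        gt = sub[sub["arm"] == "GT"]
        paired_possible = set(tr["subject_id"]) == set(gt["subject_id"]) and len(tr) >= 2
        for feat in feature_cols:
            x_tr = pd.to_numeric(tr[feat], errors="coerce").to_numpy()
            x_gt = pd.to_numeric(gt[feat], errors="coerce").to_numpy()
            entry = {"fov": fov, "feature": feat}
            try:
                t_w, p_w = ttest_tr_vs_gt(x_tr, x_gt, paired=False)
                entry.update(
                    t_welch=t_w, p_welch=p_w, significant_at_0_05=bool(p_w < ALPHA)
                )
            except ValueError:
                entry.update(t_welch=np.nan, p_welch=np.nan, significant_at_0_05=None)
            if paired_possible:
                tr_s = tr.set_index("subject_id")[feat]
                gt_s = gt.set_index("subject_id")[feat]
                common = tr_s.index.intersection(gt_s.index)
                try:
                    t_p, p_p = ttest_tr_vs_gt(
                        tr_s.loc[common].to_numpy(), gt_s.loc[common].to_numpy(), paired=True
                    )
                    entry.update(t_paired=t_p, p_paired=p_p)
                except ValueError:
                    entry.update(t_paired=np.nan, p_paired=np.nan)
            else:
                entry.update(t_paired=np.nan, p_paired=np.nan)
            out.append(entry)
    return out


def build_report(
    manifest: pd.DataFrame,
    features: pd.DataFrame,
    quality: pd.DataFrame | None = None,
    out_dir: str | Path | None = None,
    provenance: dict | None = None,
    feature_cols=FEATURES,
) -> dict:
    """Assemble the cohort report: mean±SD tables, t-tests, exclusions.

    Subjects whose TR (or GT) row is missing from the features table are
    listed under ``exclusions`` and dropped from the paired comparison; the
    run never aborts for unmatched pairs.  When ``out_dir`` is given, the
    tables are written as ``table_means.csv``, ``table_ttests.csv`` and the
    full report as ``report.json`` — deterministic given the inputs.
    """
    have = set(zip(features["subject_id"], features["arm"]))
    exclusions = []
    for subject_id in sorted(manifest["subject_id"].unique()):
        for arm in ("GT", "TR"):
            expected = ((manifest["subject_id"] == subject_id) & (manifest["arm"] == arm)).any()
            if expected and (subject_id, arm) not in have:
                exclusions.append({"subject_id": subject_id, "arm": arm, "reason": "missing features row"})

    complete = features[
        features["subject_id"].map(
            features.groupby("subject_id")["arm"].nunique().ge(2)
        )
    ]
    means = summarize(features, feature_cols=feature_cols)
    ttests = _ttest_block(complete if len(complete) else features, feature_cols)

    report = {
        "n_subjects": int(manifest["subject_id"].nunique()),
        "n_tests": len([t for t in ttests if not np.isnan(t.get("p_welch", np.nan))]),
        "alpha": ALPHA,
        "means": means.to_dict(orient="records"),
        "ttests": ttests,
        "exclusions": exclusions,
        "provenance": provenance or {},
    }
    if quality is not None and len(quality):
        report["quality"] = {
            "mean_ssim": float(pd.to_numeric(quality["ssim"]).mean()),
            "mean_pcqi": float(pd.to_numeric(quality["pcqi"]).mean()),
        }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        header = _provenance_header(provenance)
        _write_csv(means, out_dir / "table_means.csv", header)
        _write_csv(pd.DataFrame(ttests), out_dir / "table_ttests.csv", header)
        (out_dir / "report.json").write_text(json.dumps(report, indent=2, default=_json_default))
    return report


def _provenance_header(provenance: dict | None) -> str:
    from . import __version__

    prov = provenance or {}
    bits = [f"octaquant {__version__}"]
    for key in ("config_hash", "master_seed"):
        if key in prov:
            bits.append(f"{key}={prov[key]}")
    return "# " + " ".join(bits)


def _write_csv(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, index=False)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def plot_group_boxes(features: pd.DataFrame, out_path: str | Path, feature_cols=FEATURES) -> None:
    """Optional per-group boxplots of the four features (needs matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, len(feature_cols), figsize=(4 * len(feature_cols), 4))
    for ax, feat in zip(np.atleast_1d(axes), feature_cols):
        data, labels = [], []
        for (group, arm), sub in features.groupby(["group", "arm"], sort=True):
            vals = pd.to_numeric(sub[feat], errors="coerce").dropna()
            data.append(vals)
            labels.append(f"{group}\n{arm}")
        ax.boxplot(data, tick_labels=labels)
        ax.set_title(feat.upper())
    fig.tight_layout()
    fig.savefig(out_path, dpi=100)
    plt.close(fig)
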