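"""Technical-validation suite: reproducibility and bias diagnostics.

Covers the standard battery for a QC-bracketed LC-MS acquisition:
per-ion QC RSD distributions (histogram and fraction below 20%),
internal-standard RSD tables per polarity, paired t-tests on replicated
study samples (on log10 intensities, since the noise model is
multiplicative), a PCA overview of sample variance, a blank/QC carryover
ratio check, and fold-change arithmetic for interpreting mean peak-height
differences between groups.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import FeatureMatrix
from .simulate import EICSet, InjectionPlan

__all__ = [
    "duplicate_paired_ttest",
    "paired_log_ttest",
    "pca_overview",
    "PCAResult",
    "carryover_check",
    "fold_change",
    "FoldChange",
    "rsd_histogram",
    "internal_standard_rsd",
    "build_report",
]


def paired_log_ttest(
    a: pd.DataFrame, b: pd.DataFrame, min_pairs: int = 2
) -> pd.DataFrame:
    """Classical paired t-test per column on log10-transformed values.

    ``a`` and ``b`` are aligned (pairs x ions) tables of the two members of
    each replicate pair.  Pairs with a non-positive or missing member are
    dropped per ion; ions with fewer than ``min_pairs`` complete pairs get
    NaN statistics.  Zero-variance differences are degenerate: p = 1 with a
    flag rather than an error.
    """
    if list(a.columns) != list(b.columns) or len(a) != len(b):
        raise ValueError("pair tables must be aligned on ions and pairs")
    rows = []
    for ion_id in a.columns:
        x = a[ion_id].to_numpy(dtype=float)
        y = b[ion_id].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y) & (x > 0) & (y > 0)
        n = int(ok.sum())
        if n < min_pairs:
            rows.append(dict(ion_id=ion_id, n_pairs=n, t=math.nan, p=math.nan,
                             degenerate=False))
            continue
        d = np.log10(x[ok]) - np.log10(y[ok])
        sd = d.std(ddof=1)
        if sd == 0:
            rows.append(dict(ion_id=ion_id, n_pairs=n, t=0.0, p=1.0,
                             degenerate=True))
            continue
        t = d.mean() / (sd / math.sqrt(n))
        p = 2.0 * stats.t.sf(abs(t), df=n - 1)
        rows.append(dict(ion_id=ion_id, n_pairs=n, t=float(t), p=float(p),
                         degenerate=False))
    return pd.DataFrame(rows).set_index("ion_id")


def duplicate_paired_ttest(
    fm: FeatureMatrix, pairs: list[tuple[str, str]] | None = None
) -> tuple[pd.DataFrame, float]:
    """Paired t-tests across the run's replicate pairs, per ion.

    Returns the per-ion table and the fraction of testable ions with
    p > 0.05 (the non-significant fraction, a whole-pipeline reproducibility
    summary: replicates should rarely differ once drift is removed).
    """
    if pairs is None:
        pairs = fm.duplicate_pairs()
    if not pairs:
        raise ValueError("no duplicate pairs available")
    a = fm.values.loc[[p[0] for p in pairs]].reset_index(drop=True)
    b = fm.values.loc[[p[1] for p in pairs]].reset_index(drop=True)
    table = paired_log_ttest(a, b)
    tested = table["p"].dropna()
    frac_nonsig = float((tested > 0.05).mean()) if len(tested) else math.nan
    return table, frac_nonsig


@dataclasses.dataclass
class PCAResult:
    explained_pct: np.ndarray  # percent of total variance per component
    scores: pd.DataFrame  # samples x components, with sample_type column
    component_variance: np.ndarray
    total_variance: float


def pca_overview(fm: FeatureMatrix, n_components: int | None = None) -> PCAResult:
    """PCA of the log10, column-centered, unscaled non-blank matrix.

    Implemented as an SVD of the centered matrix; non-positive or missing
    cells are floored at half the smallest positive value before the log so
    the transform is defined everywhere.  A constant matrix yields zero
    variance for every component rather than an error.
    """
    values = fm.nonblank_values()
    if values.shape[0] < 3 or values.shape[1] < 2:
        raise ValueError("PCA needs at least 3 samples and 2 ions")
    arr = values.to_numpy(dtype=float)
    positive = arr[np.isfinite(arr) & (arr > 0)]
    floor = positive.min() / 2.0 if positive.size else 1.0
    arr = np.where(np.isfinite(arr), np.maximum(arr, floor), floor)
    X = np.log10(arr)
    X = X - X.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    n = X.shape[0]
    comp_var = s**2 / (n - 1)
    total = float(comp_var.sum())
    # a constant matrix leaves only rounding residue; report zero variance
    if total <= 1e-20:
        comp_var = np.zeros_like(comp_var)
        total = 0.0
    explained = (
        100.0 * comp_var / total if total > 0 else np.zeros_like(comp_var)
    )
    k = len(s) if n_components is None else min(n_components, len(s))
    scores = pd.DataFrame(
        (u * s)[:, :k],
        index=values.index,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    scores.insert(0, "sample_type", fm.samples.loc[values.index, "sample_type"])
    return PCAResult(
        explained_pct=explained[:k],
        scores=scores,
        component_variance=comp_var[:k],
        total_variance=total,
    )


def carryover_check(
    eics: EICSet, plan: InjectionPlan, threshold: float = 0.05
) -> pd.DataFrame:
    """Blank/QC total-ion signal ratio for each blank injection.

    The baseline (per-trace median) is subtracted before summing over all
    ions and retention times; blanks without a preceding QC are skipped with
    a log entry.  Ratios above ``threshold`` are flagged.
    """
    prev_qc = plan.preceding_qc()
    sample_pos = {s: i for i, s in enumerate(eics.samples)}

    def _signal(sample_id: str) -> float:
        total = 0.0
        i = sample_pos[sample_id]
        for ion_id in eics.ions:
            y = eics.traces[ion_id][i]
            total += float(np.clip(y - np.median(y), 0.0, None).sum())
        return total

    rows = []
    for blank_id in plan.of_type("blank")["sample_id"]:
        qc_id = prev_qc.get(blank_id)
        if qc_id is None:
            rows.append(dict(blank=blank_id, qc=None, ratio=math.nan,
                             flagged=False, note="no_preceding_qc"))
            continue
        qc_signal = _signal(qc_id)
        if qc_signal <= 0:
            rows.append(dict(blank=blank_id, qc=qc_id, ratio=math.nan,
                             flagged=False, note="zero_qc_signal"))
            continue
        ratio = _signal(blank_id) / qc_signal
        rows.append(dict(blank=blank_id, qc=qc_id, ratio=ratio,
                         flagged=bool(ratio > threshold), note=""))
    return pd.DataFrame(rows)


@dataclasses.dataclass(frozen=True)
class FoldChange:
    fold: float
    direction: str  # "increase" | "decrease" | "none"


def fold_change(mean_a: float, mean_b: float) -> FoldChange:
    """Fold difference between two group means of the same compound.

    fold = max/min; direction describes group a relative to group b, e.g.
    means of 25,000 vs 75,000 are a 3-fold decrease.
    """
    if not (mean_a > 0 and mean_b > 0):
        raise ValueError("fold change requires positive means")
    if mean_a == mean_b:
        return FoldChange(1.0, "none")
    fold = max(mean_a, mean_b) / min(mean_a, mean_b)
    return FoldChange(fold, "decrease" if mean_a < mean_b else "increase")


def rsd_histogram(
    rsds, bin_width: float = 5.0
) -> tuple[np.ndarray, np.ndarray, float]:
    """Bin per-ion RSDs (percent) into fixed-width bins over [0, max].

    Returns (bin_edges, counts, fraction_below_20).
    """
    values = np.asarray(pd.Series(rsds).dropna(), dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("RSDs must be finite")
    if values.size == 0:
        return np.array([0.0, bin_width]), np.array([0]), math.nan
    top = max(bin_width, float(np.ceil(values.max() / bin_width)) * bin_width)
    edges = np.arange(0.0, top + bin_width / 2, bin_width)
    counts, _ = np.histogram(values, bins=edges)
    frac_below_20 = float((values < 20.0).sum()) / len(values)
    return edges, counts, frac_below_20


def internal_standard_rsd(fm: FeatureMatrix) -> pd.DataFrame:
    """RSD of each internal standard across all non-blank samples, per mode.

    Standards are spiked at constant amount and excluded from normalization,
    so their RSD is a normalization-free probe of technical variability.
    """
    nonblank = fm.nonblank_values()
    rows = []
    for ion_id in fm.ion_ids:
        if not bool(fm.ions.loc[ion_id, "is_internal_standard"]):
            continue
        v = nonblank[ion_id].to_numpy(dtype=float)
        v = v[np.isfinite(v)]
        value = (
            100.0 * v.std(ddof=1) / v.mean() if len(v) >= 2 and v.mean() != 0 else math.nan
        )
        rows.append(dict(ion_id=ion_id, name=fm.ions.loc[ion_id, "name"],
                         mode=fm.ions.loc[ion_id, "mode"], rsd=value))
    return pd.DataFrame(rows)


def build_report(
    out_dir: str | Path,
    raw: FeatureMatrix,
    normalized: FeatureMatrix,
    qc_rsd_pre: pd.Series,
    qc_rsd_post: pd.Series,
    eics: EICSet | None = None,
    plan: InjectionPlan | None = None,
    figures: bool = True,
) -> Path:
    """Write the QC report: CSV tables, a markdown summary and figures."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    pd.DataFrame({"pre": qc_rsd_pre, "post": qc_rsd_post}).rename_axis(
        "ion_id"
    ).to_csv(out / "qc_rsd.csv")
    is_table = internal_standard_rsd(normalized)
    is_table.to_csv(out / "internal_standard_rsd.csv", index=False)

    ttest_summary = ""
    if normalized.duplicate_pairs():
        ttest, frac_nonsig = duplicate_paired_ttest(normalized)
        ttest.to_csv(out / "duplicate_ttest.csv")
        ttest_summary = (
            f"- duplicate paired t-tests: {100 * frac_nonsig:.1f}% of ions "
            "non-significant (p > 0.05)\n"
        )

    pca = pca_overview(normalized)
    pca.scores.rename_axis("sample_id").to_csv(out / "pca_scores.csv")

    carry_summary = ""
    carry = None
    if eics is not None and plan is not None:
        carry = carryover_check(eics, plan)
        carry.to_csv(out / "carryover.csv", index=False)
        flagged = int(carry["flagged"].sum())
        carry_summary = (
            f"- carryover: {flagged}/{len(carry)} blanks above threshold; "
            f"max ratio {carry['ratio'].max():.4f}\n"
        )

    edges, counts, frac20 = rsd_histogram(qc_rsd_post.dropna())
    lines = [
        "# QC report",
        "",
        f"- ions: {len(normalized.ion_ids)}; samples: {len(normalized.sample_ids)}",
        f"- median QC RSD: {qc_rsd_pre.median():.2f}% raw -> "
        f"{qc_rsd_post.median():.2f}% normalized",
        f"- fraction of ions below 20% QC RSD (normalized): {100 * frac20:.1f}%",
        f"- PC1 variance explained: {pca.explained_pct[0]:.1f}%",
    ]
    if ttest_summary:
        lines.append(ttest_summary.rstrip())
    if carry_summary:
        lines.append(carry_summary.rstrip())
    (out / "report.md").write_text("\n".join(lines) + "\n")

    if figures:
        _write_figures(out, qc_rsd_post, edges, counts, pca, is_table, carry)
    return out


def _write_figures(out, qc_rsd_post, edges, counts, pca, is_table, carry):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge",
           edgecolor="black", color="#7aa6c2")
    ax.set_xlabel("QC RSD (%)")
    ax.set_ylabel("ions")
    fig.tight_layout()
    fig.savefig(out / "rsd_histogram.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4.5, 4))
    for stype, marker in (("study", "o"), ("qc", "s")):
        sub = pca.scores[pca.scores["sample_type"] == stype]
        if {"PC1", "PC2"} <= set(sub.columns):
            ax.scatter(sub["PC1"], sub["PC2"], s=12, marker=marker, label=stype)
    ax.set_xlabel(f"PC1 ({pca.explained_pct[0]:.1f}%)")
    if len(pca.explained_pct) > 1:
        ax.set_ylabel(f"PC2 ({pca.explained_pct[1]:.1f}%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "pca_scores.png", dpi=120)
    plt.close(fig)

    if len(is_table):
        fig, ax = plt.subplots(figsize=(6, 3))
        ax.bar(is_table["ion_id"], is_table["rsd"],
               color=["#2c7fb8" if m == "positive" else "#de7065"
                      for m in is_table["mode"]])
        ax.axhline(20.0, color="grey", ls="--", lw=0.8)
        ax.set_ylabel("RSD (%)")
        ax.tick_params(axis="x", rotation=90, labelsize=6)
        fig.tight_layout()
        fig.savefig(out / "internal_standard_rsd.png", dpi=120)
        plt.close(fig)
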