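"""Count normalization, differential-expression selection, clustering, and qPCR.

Normalization follows the nCounter housekeeping convention: reference genes
whose cross-sample average count exceeds a floor (450 by default) are
retained, and every sample is rescaled so the geometric mean of the retained
housekeeping genes is identical across samples. Differential expression is
selected by per-gene two-sided Welch t-tests (on log2(x+1) by default) with
raw p ≤ 0.05 and a linear fold-change gate of ≥ 1.5 (up) or ≤ 0.66 (down);
no multiple-testing correction is applied by default, with an optional
Benjamini–Hochberg column for users who want one. Profile clustering uses
average linkage on the Pearson correlation distance (1 − r). qPCR relative
expression is the standard 2^−ΔCt against a reference gene (ATP5O by
default), with derived ratios such as the 4R/3R tau-isoform ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from organoid_quant.core_io import CountMatrix, CtTable, ValidationError

MIN_AVG_COUNT = 450.0  #: housekeeping retention floor (average count)
ALPHA = 0.05
FC_UP = 1.5
FC_DOWN = 0.66
REF_GENE = "ATP5O"


@dataclass
class NormalizationReport:
    retained_housekeeping: list[str]
    scale_factor_per_sample: dict[str, float]
    min_avg_count: float = MIN_AVG_COUNT


@dataclass
class ClusterResult:
    """Average-linkage tree over profiles with Pearson distance 1 − r."""

    linkage_matrix: np.ndarray  # scipy (n−1, 4) linkage
    leaf_order: list[int]
    labels: list[str] = field(default_factory=list)


def _geomean(x: np.ndarray, axis: int = 0) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValidationError("geometric mean requires strictly positive counts")
    return np.exp(np.log(x).mean(axis=axis))


def normalize_counts(
    cm: CountMatrix, min_avg_count: float = MIN_AVG_COUNT
) -> tuple[CountMatrix, NormalizationReport]:
    """Housekeeping geometric-mean normalization.

    Housekeeping genes with cross-sample mean count > ``min_avg_count`` are
    retained; each sample is multiplied by
    ``(grand geometric mean of the per-sample housekeeping geometric means) /
    (housekeeping geometric mean of that sample)``. After normalization the
    housekeeping geometric mean is equal across samples, which makes the
    operation idempotent.
    """
    hk = cm.counts.loc[cm.housekeeping_ids]
    retained = [g for g in cm.housekeeping_ids if hk.loc[g].mean() > min_avg_count]
    if not retained:
        raise ValidationError(
            f"no housekeeping gene passes the average-count > {min_avg_count} filter"
        )
    gm_per_sample = _geomean(cm.counts.loc[retained].to_numpy(), axis=0)
    grand = float(np.exp(np.log(gm_per_sample).mean()))
    factors = grand / gm_per_sample
    normalized = cm.counts * factors
    report = NormalizationReport(
        retained_housekeeping=retained,
        scale_factor_per_sample={s: float(f) for s, f in zip(cm.sample_labels, factors)},
        min_avg_count=min_avg_count,
    )
    out = CountMatrix(
        counts=normalized,
        group_of_sample=dict(cm.group_of_sample),
        housekeeping_ids=list(cm.housekeeping_ids),
    )
    return out, report


def select_de(
    cm_a: CountMatrix,
    cm_b: CountMatrix,
    alpha: float = ALPHA,
    fc_up: float = FC_UP,
    fc_down: float = FC_DOWN,
    log_scale: bool = True,
    equal_var: bool = True,
    add_fdr: bool = False,
) -> pd.DataFrame:
    """Per-gene two-sided t-tests plus a linear fold-change gate.

    ``cm_a`` is the reference group (A) and ``cm_b`` the comparison group
    (B); fold change is mean_B / mean_A of the (normalized) linear counts.
    Tests run on log2(x+1) by default (``log_scale=False`` tests the linear
    counts) and use the pooled-variance Student's t (the convention of
    spreadsheet-style per-gene "multiple t-tests", and exactly calibrated
    under a normal null at n = 3); ``equal_var=False`` selects Welch's
    unequal-variance variant, which is conservative at such small n. A gene
    is called *up* when p ≤ alpha and FC ≥ fc_up, *down* when p ≤ alpha and
    FC ≤ fc_down, *ns* otherwise. Raw p-values are used for the calls;
    ``add_fdr`` appends a Benjamini–Hochberg column without affecting them.
    """
    if list(cm_a.counts.index) != list(cm_b.counts.index):
        raise ValidationError("gene ids of the two groups differ")
    a = cm_a.counts.to_numpy(dtype=float)
    b = cm_b.counts.to_numpy(dtype=float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValidationError("each group needs at least 2 samples")

    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(mean_a > 0, mean_b / mean_a, np.inf)
        fc = np.where((mean_a == 0) & (mean_b == 0), 1.0, fc)

    ta = np.log2(a + 1.0) if log_scale else a
    tb = np.log2(b + 1.0) if log_scale else b
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(tb, ta, axis=1, equal_var=equal_var)
    p = np.asarray(res.pvalue, dtype=float)
    # degenerate genes: zero variance in both groups → p undefined; by
    # convention p = 1 when the means agree, p = 0 when they differ
    degen = np.isnan(p)
    if degen.any():
        equal = np.isclose(ta.mean(axis=1), tb.mean(axis=1))
        p[degen & equal] = 1.0
        p[degen & ~equal] = 0.0

    call = np.full(len(p), "ns", dtype=object)
    call[(p <= alpha) & (fc >= fc_up)] = "up"
    call[(p <= alpha) & (fc <= fc_down)] = "down"

    table = pd.DataFrame(
        {
            "mean_A": mean_a,
            "mean_B": mean_b,
            "fold_change": fc,
            "p_value": p,
            "call": call,
        },
        index=cm_a.counts.index,
    )
    if add_fdr:
        table["p_adj_bh"] = multipletests(p, method="fdr_bh")[1]
    return table


def qc_controls(
    positive_counts: np.ndarray,
    positive_inputs: np.ndarray,
    negative_counts: np.ndarray,
) -> dict:
    """QC report against spiked positive/negative controls.

    Reports the R² of counts vs known positive-control input (linearity) and
    a background level (negative-control mean + 2 SD); informational only,
    no samples are gated.
    """
    pos = np.asarray(positive_counts, dtype=float)
    inp = np.asarray(positive_inputs, dtype=float)
    r = np.corrcoef(np.log2(pos), np.log2(inp))[0, 1]
    neg = np.asarray(negative_counts, dtype=float)
    return {
        "positive_control_r2": float(r**2),
        "negative_control_background": float(neg.mean() + 2 * neg.std(ddof=1)),
    }


def cluster_profiles(
    matrix: np.ndarray | pd.DataFrame, labels: list[str] | None = None
) -> ClusterResult:
    """Hierarchical clustering with average linkage and Pearson distance.

    Rows are profiles; the pairwise distance is 1 − Pearson r (in [0, 2]).
    Zero-variance profiles make the correlation undefined and raise.
    """
    if isinstance(matrix, pd.DataFrame):
        if labels is None:
            labels = [str(i) for i in matrix.index]
        matrix = matrix.to_numpy(dtype=float)
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise ValidationError("need at least two profiles to cluster")
    if np.any(matrix.std(axis=1) == 0):
        raise ValidationError("zero-variance profile: Pearson distance undefined")
    dist = pdist(matrix, metric="correlation")
    z = linkage(dist, method="average")
    return ClusterResult(
        linkage_matrix=z,
        leaf_order=[int(i) for i in leaves_list(z)],
        labels=labels or [],
    )


def relative_expression(
    ct: CtTable,
    ref_gene: str = REF_GENE,
    ratios: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """qPCR relative expression 2^−ΔCt with optional isoform ratios.

    ΔCt = Ct_gene − Ct_ref per sample; ``ratios`` entries such as
    ``("4R", "3R")`` append rows named ``"4R/3R"`` with
    rel_expr(4R)/rel_expr(3R) = 2^−(Ct_4R − Ct_3R).
    """
    rows = []
    for sample, sub in ct.rows.groupby("sample_label", sort=False):
        ref = sub[sub.gene_id == ref_gene]
        if ref.empty:
            raise ValidationError(f"reference gene {ref_gene!r} missing for sample {sample!r}")
        ct_ref = float(ref.ct_value.iloc[0])
        rel = {}
        for _, r in sub.iterrows():
            rel[r.gene_id] = 2.0 ** -(float(r.ct_value) - ct_ref)
            rows.append({"sample_label": sample, "gene_id": r.gene_id, "rel_expr": rel[r.gene_id]})
        for num, den in ratios or []:
            if num in rel and den in rel:
                rows.append(
                    {
                        "sample_label": sample,
                        "gene_id": f"{num}/{den}",
                        "rel_expr": rel[num] / rel[den],
                    }
                )
    return pd.DataFrame(rows)
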