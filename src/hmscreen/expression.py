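"""Relative expression (ΔCq) and its significance structure.

Quantitative PCR reports a quantification cycle Cq per well; expression of a
target gene relative to a reference gene is summarised as

    ΔCq = Cq(reference) − Cq(target),

so a *higher* ΔCq means *higher* relative expression of the target (each
cycle is a doubling).  Two reference genes (RpL32 and RpS18) are assayed for
every target; they differ by an additive offset on the ΔCq scale.

Significance structure on top of ΔCq:

* a two-way fixed-effects ANOVA (gene × reference gene) checking that the
  reference genes act additively,
* per-gene one-way ANOVA across sample classes (parental species, backcross
  and introgression males, tissues), pooling the two reference genes by
  centering ΔCq within each reference,
* Scheffé's post-hoc test for all pairwise class contrasts,
* Benjamini–Hochberg FDR q-values over the pairwise tests,
* a compact letter display (classes share a letter iff not significantly
  different),
* plain mean/SE count summaries for fecundity tables.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "AnovaResult",
    "SignificanceReport",
    "compute_delta_cq",
    "primer_efficiency",
    "two_way_anova",
    "anova_per_gene",
    "scheffe_pairwise",
    "bh_fdr",
    "letter_display",
    "summarize_counts",
    "significance_reports",
    "comparison_flags",
]

CQ_COLUMNS = ("gene", "sample_class", "replicate", "reference_gene", "cq_reference", "cq_target")


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    f_statistic: float
    df_num: int
    df_den: int
    p_value: float


@dataclass
class SignificanceReport:
    """Per-gene cross-class test results.

    ``pairwise`` and ``qvalues`` are symmetric DataFrames over sample
    classes with unit diagonal; ``letters`` maps each class to its compact
    letter-display string.
    """

    gene: str
    anova: AnovaResult
    class_means: pd.Series
    pairwise: pd.DataFrame
    qvalues: pd.DataFrame | None = None
    letters: dict[str, str] = field(default_factory=dict)


def compute_delta_cq(records: pd.DataFrame) -> pd.DataFrame:
    """One ΔCq row per Cq record; non-finite Cq rows are rejected with a warning.

    The number of rejected rows is stored in ``result.attrs["n_rejected"]``.
    """
    missing = [c for c in CQ_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"Cq table lacks columns: {missing}")
    finite = np.isfinite(records["cq_reference"]) & np.isfinite(records["cq_target"])
    n_bad = int((~finite).sum())
    if n_bad:
        logger.warning("rejected %d Cq records with non-finite values", n_bad)
    out = records.loc[finite].copy()
    out["delta_cq"] = out["cq_reference"] - out["cq_target"]
    out.attrs["n_rejected"] = n_bad
    return out


def primer_efficiency(
    log10_input: Sequence[float], cq: Sequence[float]
) -> tuple[float, float]:
    """Amplification efficiency from a dilution-series standard curve.

    OLS of Cq on log10 relative template input; efficiency = 10^(−1/slope) − 1
    (1.0 = perfect doubling each cycle, slope ≈ −3.32).
    """
    x = np.asarray(log10_input, dtype=float)
    y = np.asarray(cq, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 dilution points")
    if np.ptp(x) == 0:
        raise ValueError("dilution inputs have zero variance")
    slope = stats.linregress(x, y).slope
    if slope == 0:
        raise ValueError("flat standard curve: Cq constant across dilutions")
    return float(slope), float(10 ** (-1.0 / slope) - 1.0)


def two_way_anova(dcq: pd.DataFrame) -> list[AnovaResult]:
    """Fixed-effects two-way ANOVA of ΔCq on gene, reference gene and interaction."""
    for factor in ("gene", "reference_gene"):
        if dcq[factor].nunique() < 2:
            raise ValueError(f"factor {factor!r} needs >= 2 levels")
    cells = dcq.groupby(["gene", "reference_gene"], observed=True).size()
    full = itertools.product(dcq["gene"].unique(), dcq["reference_gene"].unique())
    for cell in full:
        if cell not in cells.index:
            raise ValueError(f"empty cell (gene, reference) = {cell}")
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    model = smf.ols("delta_cq ~ C(gene) * C(reference_gene)", data=dcq).fit()
    table = sm.stats.anova_lm(model, typ=2)
    df_den = int(table.loc["Residual", "df"])
    name_map = {
        "C(gene)": "gene",
        "C(reference_gene)": "reference_gene",
        "C(gene):C(reference_gene)": "gene:reference_gene",
    }
    degenerate = float(table["sum_sq"].sum()) <= 1e-10  # zero-variance data
    results = []
    for row_name, effect in name_map.items():
        row = table.loc[row_name]
        f_stat, p = float(row["F"]), float(row["PR(>F)"])
        if degenerate:
            f_stat, p = 0.0, 1.0
        elif not np.isfinite(f_stat):
            # degenerate zero-variance data: no effect signal means F = 0
            if float(row["sum_sq"]) <= 1e-12:
                f_stat, p = 0.0, 1.0
            else:
                f_stat, p = np.inf, 0.0
        results.append(
            AnovaResult(
                effect=effect,
                f_statistic=f_stat,
                df_num=int(row["df"]),
                df_den=df_den,
                p_value=p,
            )
        )
    return results


def _pooled_gene_frame(dcq: pd.DataFrame, gene: str, pool_references: bool) -> pd.DataFrame:
    sub = dcq[dcq["gene"] == gene].copy()
    if sub.empty:
        raise ValueError(f"no ΔCq rows for gene {gene}")
    counts = sub.groupby("sample_class", observed=True).size()
    if counts.size < 2:
        raise ValueError(f"{gene}: need >= 2 sample classes")
    small = counts[counts < 2]
    if not small.empty:
        raise ValueError(f"{gene}: class(es) with < 2 replicates: {list(small.index)}")
    n_ref = sub["reference_gene"].nunique()
    if pool_references and n_ref > 1:
        sub["y"] = sub["delta_cq"] - sub.groupby("reference_gene", observed=True)[
            "delta_cq"
        ].transform("mean")
        sub.attrs["df_adjust"] = n_ref - 1
    else:
        sub["y"] = sub["delta_cq"]
        sub.attrs["df_adjust"] = 0
    return sub


def anova_per_gene(
    dcq: pd.DataFrame, gene: str, pool_references: bool = True
) -> AnovaResult:
    """One-way fixed-effects ANOVA of ΔCq across sample classes for one gene.

    With ``pool_references`` the two reference genes are pooled by centering
    ΔCq within each reference before fitting; the residual df is reduced by
    the number of centered reference means beyond the first, which under a
    balanced layout makes the fit identical to an additive
    class + reference model.  With ``pool_references=False`` the rows are
    analysed as given (use it after subsetting to a single reference gene).
    """
    sub = _pooled_gene_frame(dcq, gene, pool_references)
    y = sub["y"].to_numpy()
    classes = sub["sample_class"].to_numpy()
    labels, inverse = np.unique(classes, return_inverse=True)
    k = labels.size
    N = y.size
    grand = y.mean()
    group_means = np.array([y[inverse == g].mean() for g in range(k)])
    group_n = np.bincount(inverse)
    ss_between = float(np.sum(group_n * (group_means - grand) ** 2))
    ss_total = float(np.sum((y - grand) ** 2))
    ss_resid = max(ss_total - ss_between, 0.0)
    df_num = k - 1
    df_den = N - k - sub.attrs["df_adjust"]
    if df_den <= 0:
        raise ValueError(f"{gene}: no residual degrees of freedom")
    ms_between = ss_between / df_num
    ms_resid = ss_resid / df_den
    if ms_resid == 0:
        f_stat = 0.0 if ms_between == 0 else np.inf
        p = 1.0 if ms_between == 0 else 0.0
    else:
        f_stat = ms_between / ms_resid
        p = float(stats.f.sf(f_stat, df_num, df_den))
    return AnovaResult("sample_class", float(f_stat), df_num, df_den, p)


def scheffe_pairwise(
    dcq: pd.DataFrame, gene: str, pool_references: bool = True
) -> tuple[pd.DataFrame, pd.Series]:
    """Scheffé post-hoc p-values for all pairwise class contrasts of one gene.

    For classes i, j the statistic is
    ``S = (mean_i − mean_j)^2 / (MSE · (1/n_i + 1/n_j) · (k − 1))`` and
    ``p = P(F(k−1, df_resid) >= S)``, simultaneously valid for all contrasts.
    Returns the symmetric p-value matrix (unit diagonal) and the class means.
    If MSE is zero, p is 0 for unequal means and 1 for equal means.
    """
    sub = _pooled_gene_frame(dcq, gene, pool_references)
    y = sub["y"].to_numpy()
    classes = sub["sample_class"].to_numpy()
    labels, inverse = np.unique(classes, return_inverse=True)
    k = labels.size
    N = y.size
    group_means = np.array([y[inverse == g].mean() for g in range(k)])
    group_n = np.bincount(inverse)
    ss_resid = float(np.sum((y - group_means[inverse]) ** 2))
    df_den = N - k - sub.attrs["df_adjust"]
    mse = ss_resid / df_den
    p = np.ones((k, k))
    if mse == 0:
        logger.warning("%s: zero residual variance in Scheffé test", gene)
    for i in range(k):
        for j in range(i + 1, k):
            diff = group_means[i] - group_means[j]
            if mse == 0:
                pij = 1.0 if diff == 0 else 0.0
            else:
                s = diff**2 / (mse * (1 / group_n[i] + 1 / group_n[j]) * (k - 1))
                pij = float(stats.f.sf(s, k - 1, df_den))
            p[i, j] = p[j, i] = pij
    mat = pd.DataFrame(p, index=labels, columns=labels)
    raw_means = sub.groupby("sample_class", observed=True)["delta_cq"].mean()
    return mat, raw_means.reindex(labels)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, order-preserving with the input."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def letter_display(nonsig: pd.DataFrame) -> dict[str, str]:
    """Compact letter display from a symmetric boolean non-significance matrix.

    Two classes share at least one letter iff their entry is True
    (insert-and-absorb construction).  Letters are assigned a, b, c, ... in
    first-use order following the matrix's class order.
    """
    mat = nonsig.to_numpy(dtype=bool)
    classes = list(nonsig.index)
    k = len(classes)
    if mat.shape != (k, k) or not np.array_equal(mat, mat.T):
        raise ValueError("non-significance matrix must be square and symmetric")
    if not mat.diagonal().all():
        raise ValueError("diagonal must be True (a class is not distinct from itself)")
    groups: list[set[int]] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if mat[i, j]:
                continue
            # significant pair: split every group containing both
            new_groups: list[set[int]] = []
            for g in groups:
                if i in g and j in g:
                    new_groups.extend((g - {i}, g - {j}))
                else:
                    new_groups.append(g)
            # absorb groups contained in another
            groups = [
                g
                for g in new_groups
                if g and not any(g < h for h in new_groups if h is not g)
            ]
            # drop duplicates
            uniq = []
            for g in groups:
                if g not in uniq:
                    uniq.append(g)
            groups = uniq
    # order groups by their first class, assign letters in first-use order
    groups.sort(key=lambda g: (min(g), sorted(g)))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters: dict[str, list[str]] = {c: [] for c in classes}
    for gi, g in enumerate(groups):
        sym = alphabet[gi] if gi < 26 else f"a{gi}"
        for idx in sorted(g):
            letters[classes[idx]].append(sym)
    return {c: "".join(v) for c, v in letters.items()}


def summarize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Mean and SE (sd/√n, n−1 convention) of counts per class."""
    if not {"sample_class", "count"} <= set(counts.columns):
        raise ValueError("count table needs columns sample_class, count")
    rows = []
    for cls, grp in counts.groupby("sample_class", observed=True, sort=False):
        vals = grp["count"].to_numpy(dtype=float)
        if vals.size == 0:
            raise ValueError(f"empty class {cls}")
        if vals.size == 1:
            logger.warning("class %s has a single count; SE reported as 0", cls)
            se = 0.0
        else:
            se = float(vals.std(ddof=1) / np.sqrt(vals.size))
        rows.append({"sample_class": cls, "mean": float(vals.mean()), "se": se, "n": vals.size})
    return pd.DataFrame(rows)


def significance_reports(
    dcq: pd.DataFrame,
    alpha: float = 0.05,
    fdr_scope: str = "joint",
    pool_references: bool = True,
) -> dict[str, SignificanceReport]:
    """Full per-gene significance structure with FDR-corrected letter groups.

    ``fdr_scope="joint"`` corrects all Scheffé pairwise p-values across all
    genes as one family (the conservative reading of a global FDR policy);
    ``"per-gene"`` corrects within each gene separately.
    """
    if fdr_scope not in ("joint", "per-gene"):
        raise ValueError("fdr_scope must be 'joint' or 'per-gene'")
    reports: dict[str, SignificanceReport] = {}
    triples: list[tuple[str, str, str]] = []
    pvals: list[float] = []
    for gene in dcq["gene"].unique():
        anova = anova_per_gene(dcq, gene, pool_references=pool_references)
        mat, means = scheffe_pairwise(dcq, gene, pool_references=pool_references)
        reports[gene] = SignificanceReport(
            gene=gene, anova=anova, class_means=means, pairwise=mat
        )
        labels = list(mat.index)
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                triples.append((gene, a, b))
                pvals.append(float(mat.loc[a, b]))
    if fdr_scope == "joint":
        qvals = bh_fdr(pvals) if pvals else np.array([])
    else:
        qvals = np.empty(len(pvals))
        start = 0
        for gene, rep in reports.items():
            m = rep.pairwise.shape[0]
            n_pairs = m * (m - 1) // 2
            qvals[start : start + n_pairs] = bh_fdr(pvals[start : start + n_pairs])
            start += n_pairs
    for gene, rep in reports.items():
        qmat = pd.DataFrame(
            np.ones_like(rep.pairwise.to_numpy()),
            index=rep.pairwise.index,
            columns=rep.pairwise.columns,
        )
        rep.qvalues = qmat
    for (gene, a, b), q in zip(triples, qvals):
        reports[gene].qvalues.loc[a, b] = q
        reports[gene].qvalues.loc[b, a] = q
    for rep in reports.values():
        nonsig = rep.qvalues >= alpha
        np.fill_diagonal(nonsig.values, True)
        rep.letters = letter_display(nonsig)
    return reports


def comparison_flags(
    reports: Mapping[str, SignificanceReport],
    fertile_classes: Sequence[str],
    parent_classes: Sequence[str] = ("Dpb", "Dpp"),
    sterile_f1: str = "F1sterile",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Derive per-(gene, class) misregulation flags from significance reports.

    ``diff_from_both_parents`` is True iff the class's q-value against *each*
    parental species is below ``alpha``; ``diff_from_sterile_f1`` compares
    against the sterile F1 class the same way.
    """
    rows = []
    for gene, rep in reports.items():
        q = rep.qvalues
        for cls in fertile_classes:
            if cls not in q.index:
                raise ValueError(f"{gene}: class {cls} missing from report")
            both = all(float(q.loc[cls, p]) < alpha for p in parent_classes)
            f1 = float(q.loc[cls, sterile_f1]) < alpha if sterile_f1 in q.index else False
            rows.append(
                {
                    "gene": gene,
                    "sample_class": cls,
                    "diff_from_both_parents": both,
                    "diff_from_sterile_f1": f1,
                }
            )
    return pd.DataFrame(rows)
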