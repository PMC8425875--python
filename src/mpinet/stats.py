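"""Elementary statistical screens for expression cohorts.

Differential expression (paired / unpaired Wilcoxon), log2 fold change,
multiple-testing correction, univariate Cox screening, log-rank comparison,
one-sided Fisher enrichment, and z-score normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps

logger = logging.getLogger(__name__)

# exact Wilcoxon tails are enumerated up to this many pairs (no ties)
EXACT_WILCOXON_MAX_N = 25


@dataclass
class ExpressionCohort:
    """Genes x samples expression matrix (log2 scale) plus clinical annotations.

    ``clinical`` is indexed by sample id and may carry columns ``group``,
    ``pair_id``, ``time`` (days), ``event`` (0/1) and free covariates.
    Zero-variance genes are dropped on construction (logged).
    """

    expression: pd.DataFrame
    clinical: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        if self.expression.columns.duplicated().any():
            raise ValueError("duplicate sample ids in expression matrix")
        sd = self.expression.std(axis=1, ddof=1)
        dead = sd[(sd == 0) | sd.isna()].index.tolist()
        if dead:
            logger.info("dropping %d zero-variance genes: %s", len(dead), dead[:10])
            self.expression = self.expression.drop(index=dead)
        if len(self.clinical) and not self.clinical.index.is_unique:
            raise ValueError("duplicate sample ids in clinical table")

    @property
    def samples(self) -> list[str]:
        return list(self.expression.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.expression.index)

    def samples_in_group(self, label) -> list[str]:
        if "group" not in self.clinical.columns:
            raise ValueError("clinical table has no 'group' column")
        sel = self.clinical.index[self.clinical["group"] == label]
        return [s for s in self.samples if s in set(sel)]

    @classmethod
    def from_tsv(cls, expression_path, clinical_path=None) -> "ExpressionCohort":
        expr = pd.read_csv(expression_path, sep="\t", index_col=0)
        clin = pd.DataFrame()
        if clinical_path is not None:
            clin = pd.read_csv(clinical_path, sep="\t", index_col=0)
        return cls(expr, clin)

    def to_tsv(self, expression_path, clinical_path=None) -> None:
        self.expression.to_csv(expression_path, sep="\t")
        if clinical_path is not None:
            self.clinical.to_csv(clinical_path, sep="\t")


def log2_fold_change(values_a, values_b) -> float:
    """Difference of means of log2-scale values: mean(a) - mean(b)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("log2_fold_change requires non-empty inputs")
    return float(a.mean() - b.mean())


def adjust_pvalues(p, method: str = "BH") -> np.ndarray:
    """Benjamini-Hochberg step-up or Bonferroni adjustment."""
    p = np.asarray(p, dtype=float)
    if p.size and ((p < 0).any() or (p > 1).any()):
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    if method != "BH":
        raise ValueError(f"unknown correction method {method!r}")
    if p.size == 0:
        return p.copy()
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def _wilcoxon_signed_rank(diff: np.ndarray) -> float:
    """Two-sided signed-rank p; exact for small tie-free samples, else
    normal approximation with continuity correction (zeros dropped)."""
    d = diff[diff != 0]
    n = d.size
    if n == 0:
        return 1.0
    has_ties = np.unique(np.abs(d)).size != n
    if n <= EXACT_WILCOXON_MAX_N and not has_ties:
        return float(sps.wilcoxon(d, alternative="two-sided", method="exact").pvalue)
    if n < 3:
        return 1.0
    return float(
        sps.wilcoxon(d, alternative="two-sided", method="approx", correction=True).pvalue
    )


def paired_differential(
    cohort: ExpressionCohort, group_a, group_b, pair_col: str = "pair_id"
) -> pd.DataFrame:
    """Per-gene paired Wilcoxon signed-rank test of group_a vs group_b.

    Samples are matched through the clinical ``pair_id`` column; every
    group_a sample must have exactly one group_b partner.
    """
    a_samples = cohort.samples_in_group(group_a)
    b_samples = cohort.samples_in_group(group_b)
    if pair_col not in cohort.clinical.columns:
        raise ValueError(f"clinical table has no {pair_col!r} column for pairing")
    pair_of = cohort.clinical[pair_col]
    b_by_pair = {pair_of[s]: s for s in b_samples}
    ordered_b = []
    for s in a_samples:
        partner = b_by_pair.get(pair_of[s])
        if partner is None:
            raise ValueError(f"sample {s} ({group_a}) has no {group_b} partner")
        ordered_b.append(partner)
    if len(a_samples) < 3:
        raise ValueError("paired test requires at least 3 pairs")
    mat_a = cohort.expression[a_samples].to_numpy()
    mat_b = cohort.expression[ordered_b].to_numpy()
    diffs = mat_a - mat_b
    pvals = np.array([_wilcoxon_signed_rank(row) for row in diffs])
    l2fc = mat_a.mean(axis=1) - mat_b.mean(axis=1)
    return _differential_table(cohort.genes, l2fc, pvals)


def unpaired_differential(cohort: ExpressionCohort, group_a, group_b) -> pd.DataFrame:
    """Per-gene rank-sum (Mann-Whitney) test of group_a vs group_b."""
    a_samples = cohort.samples_in_group(group_a)
    b_samples = cohort.samples_in_group(group_b)
    if len(a_samples) < 3 or len(b_samples) < 3:
        raise ValueError("both groups need at least 3 samples")
    mat_a = cohort.expression[a_samples].to_numpy()
    mat_b = cohort.expression[b_samples].to_numpy()
    pvals = np.empty(mat_a.shape[0])
    for i in range(mat_a.shape[0]):
        a, b = mat_a[i], mat_b[i]
        if np.all(a == a[0]) and np.all(b == a[0]):
            pvals[i] = 1.0
            continue
        pvals[i] = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto").pvalue
    l2fc = mat_a.mean(axis=1) - mat_b.mean(axis=1)
    return _differential_table(cohort.genes, l2fc, pvals)


def _differential_table(genes, l2fc, pvals) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "gene": genes,
            "log2FC": l2fc,
            "p": np.clip(pvals, 0.0, 1.0),
        }
    ).set_index("gene")
    df["p_adjusted"] = adjust_pvalues(df["p"].to_numpy(), method="BH")
    df["direction"] = np.sign(df["log2FC"]).astype(int)
    return df


def cox_screen(
    cohort: ExpressionCohort,
    time_col: str = "time",
    event_col: str = "event",
    zscore_covariate: bool = True,
) -> pd.DataFrame:
    """Univariate Cox proportional-hazards screen, one fit per gene.

    The gene's (optionally z-scored) expression is the sole covariate;
    Efron tie handling; Wald p. Genes whose fit fails or that carry no
    variance are flagged rather than raising.
    """
    clin = cohort.clinical
    for col in (time_col, event_col):
        if col not in clin.columns:
            raise ValueError(f"clinical table lacks {col!r} column")
    samples = [s for s in cohort.samples if s in clin.index]
    times = clin.loc[samples, time_col].astype(float)
    events = clin.loc[samples, event_col].astype(int)
    if (times <= 0).any():
        raise ValueError("survival times must be positive")
    if events.sum() < 10:
        raise ValueError("cox_screen requires at least 10 events")
    records = []
    for gene in cohort.genes:
        x = cohort.expression.loc[gene, samples].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            records.append((gene, np.nan, np.nan, np.nan, "non_informative"))
            continue
        if zscore_covariate:
            x = (x - x.mean()) / sd
        df = pd.DataFrame({"time": times.to_numpy(), "event": events.to_numpy(), "x": x})
        try:
            cph = CoxPHFitter()
            cph.fit(df, duration_col="time", event_col="event")
            coef = float(cph.params_["x"])
            p = float(cph.summary.loc["x", "p"])
            records.append((gene, coef, float(np.exp(coef)), p, "ok"))
        except Exception as exc:  # noqa: BLE001 - flag, don't crash the screen
            logger.warning("cox fit failed for %s: %s", gene, exc)
            records.append((gene, np.nan, np.nan, np.nan, "failed"))
    return pd.DataFrame(
        records, columns=["gene", "coefficient", "hazard_ratio", "p", "status"]
    ).set_index("gene")


def logrank(
    cohort: ExpressionCohort,
    labels,
    time_col: str = "time",
    event_col: str = "event",
) -> tuple[float, float]:
    """K-group log-rank test; returns (chi-square statistic, p)."""
    labels = pd.Series(labels)
    samples = [s for s in cohort.samples if s in labels.index and s in cohort.clinical.index]
    if not samples:
        # labels may be positional over cohort samples
        if len(labels) == len(cohort.samples):
            labels = pd.Series(list(labels), index=cohort.samples)
            samples = [s for s in cohort.samples if s in cohort.clinical.index]
        else:
            raise ValueError("labels do not align with cohort samples")
    lab = labels.loc[samples]
    groups = lab.unique()
    if len(groups) < 2:
        raise ValueError("log-rank requires at least 2 groups")
    times = cohort.clinical.loc[samples, time_col].astype(float)
    events = cohort.clinical.loc[samples, event_col].astype(int)
    for g in groups:
        if events[lab == g].sum() < 1:
            raise ValueError(f"group {g!r} has no events")
    res = multivariate_logrank_test(times, lab, events)
    return float(res.test_statistic), float(res.p_value)


def fisher_enrichment_one_sided(table) -> float:
    """One-sided Fisher exact p for over-representation in cell [0, 0]."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    return float(sps.fisher_exact(t, alternative="greater")[1])


def zscore_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Standardize each gene row to mean 0, sd 1 (ddof=1)."""
    values = matrix.to_numpy(dtype=float)
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    zero = np.where(sd.ravel() == 0)[0]
    if zero.size:
        names = [matrix.index[i] for i in zero[:10]]
        raise ValueError(f"zero-variance rows cannot be z-scored: {names}")
    return pd.DataFrame((values - mu) / sd, index=matrix.index, columns=matrix.columns)
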