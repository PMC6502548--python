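"""Expression summaries and differential-expression contrasts.

The filter cascade consumes three per-gene quantities:

* **CPM** (counts per million): library-size normalised counts; a gene
  with CPM >= 1 is considered expressed.
* **avNtCov** (average nucleotide coverage): mean per-base read depth,
  ``counts * read_length / gene_length`` per replicate, reported as
  mean +/- sample sd over replicates.
* **log2FC / FDR** for a named (test, reference) condition pair:
  ``log2((meanCPM_test + pc) / (meanCPM_ref + pc))`` with a pseudocount,
  an exact conditional binomial test on pooled replicate counts (offset
  by the library-size ratio), and Benjamini-Hochberg FDR over all genes.

The binomial test conditions on the total pooled count of a gene across
both groups: under the null of equal concentration, the test-group share
is Binomial(n, L_t / (L_t + L_r)) where L_t, L_r are summed library
sizes.  This is the exact two-sample Poisson comparison and is a
self-contained substitute for a full NB-GLM differential-expression fit;
it does not model biological overdispersion, which is acceptable for the
two-replicate design the cascade filters on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .conditions import CONDITIONS
from .errors import ValidationError

UP_MODES = ("lenient", "strict")

#: Thresholds of the strict up-regulation call.
STRICT_LOG2FC = 0.58
STRICT_FDR = 0.05


@dataclass
class ExpressionMatrix:
    """Per-gene read counts for the five-condition, two-replicate design.

    Parameters
    ----------
    gene_ids:
        Ordered gene identifiers (rows of ``counts``).
    counts:
        Non-negative integer matrix, genes x samples.
    sample_names:
        Column labels, e.g. ``"NW186_minusFe_a_r1"``.
    sample_conditions:
        Display condition label per sample (five-label vocabulary).
    gene_lengths:
        Gene length in nt per gene (> 0).
    read_length:
        Read length in nt used for the coverage conversion.
    """

    gene_ids: list[str]
    counts: np.ndarray
    sample_names: list[str]
    sample_conditions: list[str]
    gene_lengths: np.ndarray
    read_length: int = 100

    _gene_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_lengths = np.asarray(self.gene_lengths, dtype=float)
        n_genes, n_samples = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValidationError("gene_ids length does not match counts rows")
        if len(self.sample_names) != n_samples or len(self.sample_conditions) != n_samples:
            raise ValidationError("sample annotation length does not match counts columns")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValidationError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValidationError("counts must be non-negative")
        unknown = set(self.sample_conditions) - set(CONDITIONS)
        if unknown:
            raise ValidationError(
                f"unknown condition labels {sorted(unknown)}; valid: {list(CONDITIONS)}"
            )
        if (self.gene_lengths <= 0).any():
            raise ValidationError("gene_lengths must be positive")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        if len(self._gene_index) != n_genes:
            raise ValidationError("duplicate gene ids")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def conditions(self) -> list[str]:
        """Distinct condition labels present, in canonical order."""
        present = set(self.sample_conditions)
        return [c for c in CONDITIONS if c in present]

    def samples_of(self, condition: str) -> np.ndarray:
        """Column indices of the replicates of ``condition``."""
        idx = np.flatnonzero(np.asarray(self.sample_conditions) == np.asarray(condition))
        if idx.size == 0:
            raise ValidationError(
                f"condition {condition!r} not present; available: {self.conditions}"
            )
        return idx

    def gene_row(self, gene: str) -> int:
        try:
            return self._gene_index[gene]
        except KeyError:
            raise ValidationError(f"unknown gene {gene!r}") from None


def cpm(m: ExpressionMatrix) -> np.ndarray:
    """Counts-per-million matrix (genes x samples).

    Each column is scaled by its library size (column sum) times 1e6, so
    every column sums to exactly one million.
    """
    libsize = m.counts.sum(axis=0).astype(float)
    zero = np.flatnonzero(libsize == 0)
    if zero.size:
        names = [m.sample_names[i] for i in zero]
        raise ValidationError(f"zero-total sample(s): {names}")
    return m.counts / libsize * 1e6


def expressed(m: ExpressionMatrix, threshold: float = 1.0) -> np.ndarray:
    """Boolean per-gene vector: mean CPM across all samples >= threshold."""
    return cpm(m).mean(axis=1) >= threshold


def av_nt_cov(m: ExpressionMatrix, condition: str) -> pd.DataFrame:
    """Average nucleotide coverage of one condition.

    Per replicate, coverage = counts * read_length / gene_length; returns
    a DataFrame indexed by gene with columns ``mean`` and ``sd`` (sample
    sd over replicates; 0 when the condition has a single replicate).
    """
    idx = m.samples_of(condition)
    cov = m.counts[:, idx] * m.read_length / m.gene_lengths[:, None]
    mean = cov.mean(axis=1)
    sd = cov.std(axis=1, ddof=1) if idx.size > 1 else np.zeros(m.n_genes)
    return pd.DataFrame({"mean": mean, "sd": sd}, index=m.gene_ids)


@dataclass
class ContrastResult:
    """Per-gene differential expression for one (test, reference) pair.

    ``table`` is indexed by gene id with columns ``log2fc``, ``pvalue``,
    ``fdr``, ``cov_test_mean``, ``cov_test_sd``, ``cov_ref_mean``,
    ``cov_ref_sd``.
    """

    contrast: tuple[str, str]
    table: pd.DataFrame

    @property
    def log2fc(self) -> pd.Series:
        return self.table["log2fc"]

    @property
    def fdr(self) -> pd.Series:
        return self.table["fdr"]

    def gene(self, gene_id: str) -> pd.Series:
        if gene_id not in self.table.index:
            raise ValidationError(f"unknown gene {gene_id!r}")
        return self.table.loc[gene_id]


def contrast(
    m: ExpressionMatrix, test: str, ref: str, pseudocount: float = 0.5
) -> ContrastResult:
    """Differential expression of ``test`` vs ``ref``.

    log2FC is computed on replicate-mean CPM with a symmetric pseudocount
    (finite for all-zero genes); the p-value is the exact conditional
    binomial test on pooled replicate counts with the library-size ratio
    as the null proportion; FDR is Benjamini-Hochberg over all genes in
    the matrix.
    """
    if test == ref:
        raise ValidationError("test and reference conditions must differ")
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    ti, ri = m.samples_of(test), m.samples_of(ref)
    c = cpm(m)
    mean_t = c[:, ti].mean(axis=1)
    mean_r = c[:, ri].mean(axis=1)
    log2fc = np.log2((mean_t + pseudocount) / (mean_r + pseudocount))

    lib = m.counts.sum(axis=0).astype(float)
    lt, lr = lib[ti].sum(), lib[ri].sum()
    p0 = lt / (lt + lr)
    xt = m.counts[:, ti].sum(axis=1)
    xr = m.counts[:, ri].sum(axis=1)
    pvals = np.ones(m.n_genes)
    for i in range(m.n_genes):
        n = int(xt[i] + xr[i])
        if n > 0:
            pvals[i] = stats.binomtest(int(xt[i]), n, p0).pvalue
    fdr = multipletests(pvals, method="fdr_bh")[1]

    cov_t = av_nt_cov(m, test)
    cov_r = av_nt_cov(m, ref)
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "pvalue": pvals,
            "fdr": fdr,
            "cov_test_mean": cov_t["mean"].to_numpy(),
            "cov_test_sd": cov_t["sd"].to_numpy(),
            "cov_ref_mean": cov_r["mean"].to_numpy(),
            "cov_ref_sd": cov_r["sd"].to_numpy(),
        },
        index=m.gene_ids,
    )
    return ContrastResult(contrast=(test, ref), table=table)


def is_upregulated(cr: ContrastResult, gene: str, mode: str = "lenient") -> bool:
    """Up-regulation call for one gene.

    lenient: log2FC > 0.  strict: log2FC >= 0.58 and FDR <= 0.05 (the
    thresholds of the genome-wide differential-expression summary).
    """
    if mode not in UP_MODES:
        raise ValidationError(f"mode must be one of {UP_MODES}, got {mode!r}")
    row = cr.gene(gene)
    if mode == "lenient":
        return bool(row["log2fc"] > 0)
    return bool(row["log2fc"] >= STRICT_LOG2FC and row["fdr"] <= STRICT_FDR)
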