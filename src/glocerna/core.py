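"""The GloceRNA scorer.

A candidate lncRNA-PCG pair is called a functional ceRNA when it passes
two direction-consistency criteria computed on per-patient log2 fold
changes e = log2(tumor) - log2(normal):

* **local** — the DEC score, the number of matched samples in which both
  genes move in the same direction beyond a fold-change threshold
  (per-sample score +1 if both e > t, -1 if both e < -t, else 0; DEC is
  the count of non-zero samples), must strictly exceed ``dec_cutoff``;
* **global** — the Pearson correlation of the two genes' log2FC profiles
  across patients must be strictly positive with a significant p-value.

All cutoffs are strict: with defaults, DEC > 5 means at least 6 samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import (
    CohortSizeError,
    ConfigError,
    DomainError,
    UndefinedCorrelationError,
    ValidationError,
)
from .pairing import CandidatePair, shared_mirna_test
from .types import (
    InteractionSet,
    MatchedExpressionMatrix,
    RelativeExpressionMatrix,
)

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "lncrna_id",
    "pcg_id",
    "shared_mirna_count",
    "dec_score",
    "cor",
    "p_value",
    "functional",
]


@dataclass
class GloceRNAConfig:
    """Decision thresholds for the functional-ceRNA call.

    fc_threshold
        log2 fold-change magnitude both genes must exceed for a sample to
        count as direction-consistent (strict; default 1, i.e. 2-fold).
    dec_cutoff
        minimal DEC score, strict (default 5: a pair needs consistent
        direction in more than 5 matched samples).
    cor_cutoff
        minimal Pearson correlation, strict (default 0).
    p_cutoff
        maximal correlation p-value, strict (default 0.05).
    pseudocount
        added to every expression value before log2; default 0 with a
        hard error on non-positive values (0.01 recommended for
        count-derived data).
    two_sided
        p-value sidedness for the correlation test; the published
        criterion pairs a two-sided p with cor > 0.
    """

    fc_threshold: float = 1.0
    dec_cutoff: int = 5
    cor_cutoff: float = 0.0
    p_cutoff: float = 0.05
    pseudocount: float = 0.0
    two_sided: bool = True

    def __post_init__(self) -> None:
        if self.fc_threshold <= 0:
            raise ConfigError("fc_threshold must be > 0")
        if not (0 < self.p_cutoff < 1):
            raise ConfigError("p_cutoff must lie in (0, 1)")
        if self.dec_cutoff < 0 or int(self.dec_cutoff) != self.dec_cutoff:
            raise ConfigError("dec_cutoff must be a non-negative integer")
        if self.pseudocount < 0:
            raise ConfigError("pseudocount must be >= 0")


def relative_expression(
    matrix: MatchedExpressionMatrix, pseudocount: float = 0.0
) -> RelativeExpressionMatrix:
    """Per-patient log2 fold change, tumor minus normal, for every gene."""
    normal = matrix.normal.to_numpy(dtype=float) + pseudocount
    tumor = matrix.tumor.to_numpy(dtype=float) + pseudocount
    if (normal <= 0).any() or (tumor <= 0).any():
        raise DomainError(
            "log2 fold change undefined for non-positive expression; "
            "supply a pseudocount (e.g. 0.01) for zero-containing data"
        )
    e = pd.DataFrame(
        np.log2(tumor) - np.log2(normal),
        index=matrix.gene_ids,
        columns=matrix.patient_ids,
    )
    return RelativeExpressionMatrix(e=e, pseudocount=pseudocount)


def dec_sample(e_l: float, e_g: float, fc_threshold: float = 1.0) -> int:
    """Per-sample direction-consistency score of one pair: +1 when both
    log2FC values strictly exceed the threshold, -1 when both fall
    strictly below its negative, 0 otherwise."""
    if not (math.isfinite(e_l) and math.isfinite(e_g)):
        raise ValidationError("non-finite log2FC input")
    if e_l > fc_threshold and e_g > fc_threshold:
        return 1
    if e_l < -fc_threshold and e_g < -fc_threshold:
        return -1
    return 0


def dec_score(
    rel: RelativeExpressionMatrix,
    lncrna_id: str,
    pcg_id: str,
    fc_threshold: float = 1.0,
) -> int:
    """DEC score: the number of patients whose per-sample score is non-zero."""
    e_l = rel.row(lncrna_id)
    e_g = rel.row(pcg_id)
    up = (e_l > fc_threshold) & (e_g > fc_threshold)
    down = (e_l < -fc_threshold) & (e_g < -fc_threshold)
    return int(up.sum() + down.sum())


def _pearson_p(r: np.ndarray, n: int, two_sided: bool = True) -> np.ndarray:
    """p-value of Pearson r via t = r * sqrt((n-2)/(1-r^2)), n-2 df."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 0.0))
    tail = stats.t.sf(np.abs(t), df=n - 2)
    return np.minimum((2.0 if two_sided else 1.0) * tail, 1.0)


def global_correlation(
    rel: RelativeExpressionMatrix,
    lncrna_id: str,
    pcg_id: str,
    two_sided: bool = True,
) -> tuple[float, float]:
    """Pearson correlation of the pair's log2FC profiles across patients
    and its p-value (t-distributed with n-2 degrees of freedom)."""
    n = rel.n_patients
    if n < 3:
        raise CohortSizeError(f"correlation needs >= 3 matched samples, got {n}")
    e_l = rel.row(lncrna_id)
    e_g = rel.row(pcg_id)
    if np.ptp(e_l) == 0 or np.ptp(e_g) == 0:
        raise UndefinedCorrelationError(
            f"zero variance for pair ({lncrna_id}, {pcg_id}); "
            "correlation undefined, pair must be excluded"
        )
    dl = e_l - e_l.mean()
    dg = e_g - e_g.mean()
    r = float(dl @ dg / math.sqrt((dl @ dl) * (dg @ dg)))
    p = float(_pearson_p(np.array([r]), n, two_sided)[0])
    return r, p


def classify_pair(
    dec: int, cor: float, p: float, config: GloceRNAConfig | None = None
) -> bool:
    """Functional-ceRNA decision: all three cutoffs strict."""
    config = config or GloceRNAConfig()
    return bool(
        dec > config.dec_cutoff and cor > config.cor_cutoff and p < config.p_cutoff
    )


def _pair_arrays(
    rel: RelativeExpressionMatrix, pairs: list[CandidatePair]
) -> tuple[list[CandidatePair], list[CandidatePair]]:
    present = set(rel.gene_ids)
    kept, skipped = [], []
    for p in pairs:
        (kept if p.lncrna_id in present and p.pcg_id in present else skipped).append(p)
    return kept, skipped


def run_glocerna(
    matrix: MatchedExpressionMatrix,
    pairs: list[CandidatePair],
    config: GloceRNAConfig | None = None,
) -> pd.DataFrame:
    """Score every candidate pair and call functional ceRNAs.

    Returns a DataFrame with one row per scoreable pair, sorted by
    (lncrna_id, pcg_id), columns ``lncrna_id, pcg_id,
    shared_mirna_count, dec_score, cor, p_value, functional``. Pairs
    whose genes are absent from the matrix, or whose log2FC profile has
    zero variance, are excluded and counted in ``df.attrs``.
    """
    config = config or GloceRNAConfig()
    if matrix.n_patients < 3:
        raise CohortSizeError(
            f"GloceRNA needs >= 3 matched samples, got {matrix.n_patients}"
        )
    rel = relative_expression(matrix, config.pseudocount)
    kept, skipped = _pair_arrays(rel, pairs)
    if skipped:
        logger.warning("skipping %d pairs with genes absent from matrix", len(skipped))

    n = rel.n_patients
    e = rel.e.to_numpy(dtype=float)
    row_of = {g: i for i, g in enumerate(rel.gene_ids)}
    variable = np.ptp(e, axis=1) > 0

    scoreable: list[CandidatePair] = []
    excluded_zero_var = 0
    li, gi = [], []
    for p in kept:
        il, ig = row_of[p.lncrna_id], row_of[p.pcg_id]
        if not (variable[il] and variable[ig]):
            excluded_zero_var += 1
            continue
        scoreable.append(p)
        li.append(il)
        gi.append(ig)

    if scoreable:
        el = e[li]  # (n_pairs, n)
        eg = e[gi]
        t = config.fc_threshold
        dec = ((el > t) & (eg > t)).sum(axis=1) + ((el < -t) & (eg < -t)).sum(axis=1)
        dl = el - el.mean(axis=1, keepdims=True)
        dg = eg - eg.mean(axis=1, keepdims=True)
        denom = np.sqrt((dl * dl).sum(axis=1) * (dg * dg).sum(axis=1))
        cor = (dl * dg).sum(axis=1) / denom
        pvals = _pearson_p(cor, n, config.two_sided)
        functional = (
            (dec > config.dec_cutoff)
            & (cor > config.cor_cutoff)
            & (pvals < config.p_cutoff)
        )
        df = pd.DataFrame(
            {
                "lncrna_id": [p.lncrna_id for p in scoreable],
                "pcg_id": [p.pcg_id for p in scoreable],
                "shared_mirna_count": [len(p.shared_mirnas) for p in scoreable],
                "dec_score": dec.astype(int),
                "cor": cor,
                "p_value": pvals,
                "functional": functional,
            }
        )
        df = df.sort_values(["lncrna_id", "pcg_id"], kind="mergesort").reset_index(
            drop=True
        )
    else:
        df = pd.DataFrame(columns=RESULT_COLUMNS)

    df.attrs["n_tested"] = len(scoreable)
    df.attrs["n_skipped_absent"] = len(skipped)
    df.attrs["n_excluded_zero_variance"] = excluded_zero_var
    df.attrs["n_functional"] = int(df["functional"].sum()) if len(df) else 0
    logger.info(
        "GloceRNA: %d tested, %d functional, %d skipped, %d zero-variance",
        df.attrs["n_tested"],
        df.attrs["n_functional"],
        df.attrs["n_skipped_absent"],
        df.attrs["n_excluded_zero_variance"],
    )
    return df


def ce_lncrnas(results: pd.DataFrame) -> list[str]:
    """Distinct lncRNAs of functional pairs (the functional ce-lncRNAs)."""
    if not len(results):
        return []
    return sorted(results.loc[results["functional"], "lncrna_id"].unique())


def baseline_identify(
    matrix: MatchedExpressionMatrix,
    pairs: list[CandidatePair],
    interactions: InteractionSet | None = None,
    de_fdr: float = 0.05,
    use_hyper: bool = False,
    cor_fdr: float = 0.05,
    use_relative: bool = True,
    pseudocount: float = 0.0,
    universe_size: int | None = None,
) -> pd.DataFrame:
    """Traditional ceRNA identification, for comparison with GloceRNA.

    A pair passes iff (i) Pearson cor > 0 with Benjamini-Hochberg FDR <
    ``cor_fdr`` across all tested pairs; (ii) both genes are
    differentially expressed by a paired two-sided t-test on log2
    expression (tumor vs normal) at BH FDR < ``de_fdr``; and, when
    ``use_hyper``, (iii) the shared-miRNA hypergeometric test passes BH
    FDR < 0.05 — otherwise sharing at least one miRNA suffices (which
    every candidate pair does by construction).

    The correlation is computed on relative (log2FC) profiles by
    default; ``use_relative=False`` correlates absolute tumor
    expression instead.
    """
    if matrix.n_patients < 3:
        raise CohortSizeError(
            f"baseline needs >= 3 matched samples, got {matrix.n_patients}"
        )
    rel = relative_expression(matrix, pseudocount)
    kept, skipped = _pair_arrays(rel, pairs)
    n = matrix.n_patients

    # per-gene paired DE on log2 expression (stand-in for SAM/Limma)
    log_n = np.log2(matrix.normal.to_numpy(dtype=float) + pseudocount)
    log_t = np.log2(matrix.tumor.to_numpy(dtype=float) + pseudocount)
    with np.errstate(invalid="ignore"):
        de_res = stats.ttest_rel(log_t, log_n, axis=1)
    de_p = pd.Series(de_res.pvalue, index=matrix.gene_ids).fillna(1.0)
    de_q = pd.Series(
        multipletests(de_p.to_numpy(), method="fdr_bh")[1], index=matrix.gene_ids
    )

    source = rel.e if use_relative else matrix.tumor
    arr = source.to_numpy(dtype=float)
    row_of = {g: i for i, g in enumerate(source.index)}
    variable = np.ptp(arr, axis=1) > 0

    scoreable = [
        p for p in kept if variable[row_of[p.lncrna_id]] and variable[row_of[p.pcg_id]]
    ]
    if not scoreable:
        df = pd.DataFrame(columns=RESULT_COLUMNS)
        df.attrs["n_tested"] = 0
        return df

    el = arr[[row_of[p.lncrna_id] for p in scoreable]]
    eg = arr[[row_of[p.pcg_id] for p in scoreable]]
    dl = el - el.mean(axis=1, keepdims=True)
    dg = eg - eg.mean(axis=1, keepdims=True)
    cor = (dl * dg).sum(axis=1) / np.sqrt(
        (dl * dl).sum(axis=1) * (dg * dg).sum(axis=1)
    )
    cor_p = _pearson_p(cor, n)
    cor_q = multipletests(cor_p, method="fdr_bh")[1]
    pass_cor = (cor > 0) & (cor_q < cor_fdr)

    de_pass_lnc = de_q.loc[[p.lncrna_id for p in scoreable]].to_numpy() < de_fdr
    de_pass_pcg = de_q.loc[[p.pcg_id for p in scoreable]].to_numpy() < de_fdr
    pass_de = de_pass_lnc & de_pass_pcg

    if use_hyper:
        if interactions is None:
            raise ConfigError("use_hyper requires the InteractionSet")
        hyper = shared_mirna_test(scoreable, interactions, universe_size)
        pass_hyper = hyper["q_value"].to_numpy() < 0.05
    else:
        pass_hyper = np.ones(len(scoreable), dtype=bool)

    functional = pass_cor & pass_de & pass_hyper
    df = pd.DataFrame(
        {
            "lncrna_id": [p.lncrna_id for p in scoreable],
            "pcg_id": [p.pcg_id for p in scoreable],
            "shared_mirna_count": [len(p.shared_mirnas) for p in scoreable],
            "dec_score": np.nan,
            "cor": cor,
            "p_value": cor_p,
            "functional": functional,
        }
    ).sort_values(["lncrna_id", "pcg_id"], kind="mergesort").reset_index(drop=True)
    df.attrs["n_tested"] = len(scoreable)
    df.attrs["n_skipped_absent"] = len(skipped)
    df.attrs["n_functional"] = int(functional.sum())
    return df
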