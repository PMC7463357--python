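"""Candidate lncRNA-PCG pair construction from shared miRNA targeting.

A lncRNA and a PCG become a candidate competing-endogenous-RNA pair when
at least one miRNA targets both (the sponge premise). The sharing itself
can be scored with an upper-tail hypergeometric test, used by the
traditional identification schemes.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .exceptions import ConsistencyError
from .types import LNCRNA, PCG, InteractionSet


@dataclass(frozen=True)
class CandidatePair:
    """A lncRNA-PCG pair sharing at least one miRNA."""

    lncrna_id: str
    pcg_id: str
    shared_mirnas: frozenset[str]

    def __post_init__(self) -> None:
        if not self.shared_mirnas:
            raise ConsistencyError(
                f"candidate pair ({self.lncrna_id}, {self.pcg_id}) shares no miRNA"
            )


def build_candidate_pairs(interactions: InteractionSet) -> list[CandidatePair]:
    """Enumerate all lncRNA x PCG pairs with a non-empty shared miRNA set.

    Iterates over miRNAs rather than gene pairs, so the cost scales with
    the number of co-targeting events, not with |lncRNA| x |PCG|.
    """
    lnc_by_mirna: dict[str, set[str]] = {}
    pcg_by_mirna: dict[str, set[str]] = {}
    for mirna, target, cls in interactions.edges:
        d = lnc_by_mirna if cls == LNCRNA else pcg_by_mirna
        d.setdefault(mirna, set()).add(target)

    shared: dict[tuple[str, str], set[str]] = {}
    for mirna in lnc_by_mirna.keys() & pcg_by_mirna.keys():
        for lnc in lnc_by_mirna[mirna]:
            for pcg in pcg_by_mirna[mirna]:
                shared.setdefault((lnc, pcg), set()).add(mirna)

    return [
        CandidatePair(lnc, pcg, frozenset(mirnas))
        for (lnc, pcg), mirnas in sorted(shared.items())
    ]


def shared_mirna_test(
    pairs: list[CandidatePair],
    interactions: InteractionSet,
    universe_size: int | None = None,
) -> pd.DataFrame:
    """Hypergeometric significance of shared-miRNA counts for each pair.

    For a pair with ``k`` shared miRNAs, lncRNA targeted by ``K`` miRNAs
    and PCG targeted by ``nq``, out of ``N`` miRNAs in the universe, the
    p-value is the upper tail P(X >= k) when drawing ``nq`` from ``N``
    with ``K`` successes. ``q_value`` is Benjamini-Hochberg across all
    tested pairs.

    The universe defaults to the number of distinct miRNAs in the
    interaction set — the natural sampling frame of the sharing test.
    """
    lnc_mirnas = interactions.target_to_mirnas(LNCRNA)
    pcg_mirnas = interactions.target_to_mirnas(PCG)
    if universe_size is None:
        universe_size = len(interactions.mirnas)

    rows = []
    for pair in pairs:
        big_k = len(lnc_mirnas.get(pair.lncrna_id, set()))
        nq = len(pcg_mirnas.get(pair.pcg_id, set()))
        k = len(pair.shared_mirnas)
        if k > min(big_k, nq):
            raise ConsistencyError(
                f"pair ({pair.lncrna_id}, {pair.pcg_id}): shared count {k} "
                f"exceeds marginals ({big_k}, {nq})"
            )
        if universe_size < max(big_k, nq):
            raise ConsistencyError(
                f"universe {universe_size} smaller than marginal "
                f"max({big_k}, {nq})"
            )
        p = float(hypergeom.sf(k - 1, universe_size, big_k, nq))
        rows.append(
            {
                "lncrna_id": pair.lncrna_id,
                "pcg_id": pair.pcg_id,
                "k": k,
                "K": big_k,
                "nq": nq,
                "N": universe_size,
                "p_value": min(p, 1.0),
            }
        )
    df = pd.DataFrame(
        rows, columns=["lncrna_id", "pcg_id", "k", "K", "nq", "N", "p_value"]
    )
    if len(df):
        df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    else:
        df["q_value"] = pd.Series(dtype=float)
    return df
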