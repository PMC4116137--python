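"""Contact-conservation consensus and consensus-based decoy ranking.

For an ensemble of docking decoys of one complex, every intermolecular
residue contact gets a conservation rate — the fraction of decoys in which
it occurs.  A decoy's consensus score is the mean conservation rate of its
own contacts, so decoys that realise the ensemble's most frequently
observed interface score highest (the CONSRANK statistic).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .contacts import ContactMap, PairKey


@dataclass
class ConsensusMap:
    """Contact -> conservation rate over an ensemble of ``n_models`` decoys."""

    rates: dict[PairKey, float]
    n_models: int
    cutoff: float


@dataclass
class RankTable:
    """Deterministic decoy ranking: score descending, ties by label ascending."""

    rows: list[tuple[str, float, int]]  # (model_label, score, n_contacts)

    def position(self, label: str) -> int:
        """1-based rank of a model."""
        for i, (lab, _, _) in enumerate(self.rows, start=1):
            if lab == label:
                return i
        raise KeyError(label)

    @property
    def top(self) -> str:
        return self.rows[0][0]


def _check_ensemble(maps: list[ContactMap]) -> float:
    if len(maps) < 2:
        raise ValueError("an ensemble needs at least 2 contact maps")
    cutoffs = {m.cutoff for m in maps}
    if len(cutoffs) > 1:
        raise ValueError(f"mixed cutoffs in ensemble: {sorted(cutoffs)}")
    return cutoffs.pop()


def consensus(maps: list[ContactMap]) -> ConsensusMap:
    """Conservation rate of every contact observed anywhere in the ensemble."""
    cutoff = _check_ensemble(maps)
    counts: dict[PairKey, int] = {}
    for m in maps:
        for pair in m.pairs:
            counts[pair] = counts.get(pair, 0) + 1
    n = len(maps)
    return ConsensusMap({p: k / n for p, k in counts.items()}, n, cutoff)


def conserved_contacts(
    c: ConsensusMap, threshold: float = 0.25
) -> list[tuple[PairKey, float]]:
    """Contacts with rate >= *threshold*, sorted by (-rate, pair key)."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    kept = [(p, r) for p, r in c.rates.items() if r >= threshold]
    return sorted(kept, key=lambda pr: (-pr[1], pr[0]))


def consrank_score(m: ContactMap, c: ConsensusMap, normalized: bool = True) -> float:
    """Mean (or, with ``normalized=False``, summed) conservation rate of a decoy's contacts."""
    if abs(m.cutoff - c.cutoff) > 1e-9:
        raise ValueError(f"cutoff mismatch: map {m.cutoff} vs consensus {c.cutoff}")
    if not m.contacts:
        warnings.warn(f"model {m.model_label!r} has no contacts; score 0")
        return 0.0
    total = sum(c.rates.get(pair, 0.0) for pair in m.pairs)
    return total / len(m.contacts) if normalized else total


def rank_models(
    maps: list[ContactMap], leave_one_out: bool = False, normalized: bool = True
) -> RankTable:
    """Score every decoy against the ensemble consensus and order them.

    With ``leave_one_out=True`` each decoy is scored against the consensus
    of the *other* decoys (its own contribution to every rate removed);
    the default includes the decoy itself, as appropriate for large
    ensembles of cluster centroids.
    """
    cons = consensus(maps)
    n = cons.n_models
    rows = []
    for m in maps:
        if leave_one_out:
            if n < 3:
                raise ValueError("leave-one-out needs at least 3 models")
            rates = {p: (cons.rates[p] * n - 1) / (n - 1) for p in m.pairs}
            loo = ConsensusMap(rates, n - 1, cons.cutoff)
            score = consrank_score(m, loo, normalized)
        else:
            score = consrank_score(m, cons, normalized)
        rows.append((m.model_label, score, len(m.contacts)))
    rows.sort(key=lambda r: (-r[1], r[0]))
    return RankTable(rows)
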