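"""Gene-set enrichment with Fisher's exact test and a rank-deviation z-score.

Terms are scored three ways, mirroring common enrichment services: a one-sided
over-representation p from the hypergeometric distribution, a z-score that
measures how far a term's rank (by ascending p) deviates from its expected
rank under random gene sets of the same size, and the combined score
c = ln(p) * z, which is large and positive for terms that are both highly
significant and much better-ranked than chance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .differential import bh_adjust
from .errors import ParameterError
from .omics_io import GeneSetLibrary


def fisher_pvalue(
    module_genes: Iterable[str],
    term_genes: Iterable[str],
    universe: Iterable[str],
) -> float:
    """One-sided over-representation p-value, exact rational summation.

    P(X >= k) under Hypergeometric(N=|universe|, K=|term|, n=|module|) with
    k the observed overlap; k = 0 always gives exactly 1.
    """
    universe = frozenset(universe)
    module = frozenset(module_genes)
    term = frozenset(term_genes)
    if not universe:
        raise ParameterError("universe must be nonempty")
    if not module <= universe:
        raise ParameterError("module genes must lie within the universe")
    if not term <= universe:
        raise ParameterError("term genes must lie within the universe")
    n_univ, n_term, n_mod = len(universe), len(term), len(module)
    k = len(module & term)
    if k == 0:
        return 1.0
    total = math.comb(n_univ, n_mod)
    tail = sum(
        math.comb(n_term, j) * math.comb(n_univ - n_term, n_mod - j)
        for j in range(k, min(n_term, n_mod) + 1)
    )
    return float(Fraction(tail, total))


def _z(observed_rank: float, null_mean: float, null_sd: float) -> float:
    return (observed_rank - null_mean) / max(null_sd, 1e-9)


def _term_ranks(
    library: GeneSetLibrary, genes: frozenset, universe: frozenset
) -> np.ndarray:
    pvals = [
        fisher_pvalue(genes, library[t], universe) for t in library.terms
    ]
    return stats.rankdata(pvals, method="average")


def rank_zscore(
    library: GeneSetLibrary,
    module_genes: Iterable[str],
    universe: Iterable[str],
    n_permutations: int = 100,
    seed: int = 0,
) -> dict[str, tuple[float, float]]:
    """Deviation of each term's observed rank from its permutation-null rank.

    Null ranks come from ``n_permutations`` random gene sets of the module's
    size drawn from the universe (seeded); z = (rank - null mean) / null sd
    with the sd floored at 1e-9.
    """
    if n_permutations < 10:
        raise ParameterError("n_permutations must be >= 10")
    universe = frozenset(universe)
    module = frozenset(module_genes)
    if len(module) > len(universe):
        raise ParameterError("module larger than the universe")
    if not module <= universe:
        raise ParameterError("module genes must lie within the universe")
    observed = _term_ranks(library, module, universe)
    rng = np.random.default_rng(seed)
    sorted_universe = sorted(universe)
    null = np.empty((n_permutations, len(library.terms)))
    for i in range(n_permutations):
        draw = rng.choice(
            len(sorted_universe), size=len(module), replace=False
        )
        random_set = frozenset(sorted_universe[j] for j in draw)
        null[i] = _term_ranks(library, random_set, universe)
    mean = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)
    return {
        t: (float(observed[i]), _z(observed[i], mean[i], sd[i]))
        for i, t in enumerate(library.terms)
    }


def combined_score(p: float, z: float) -> float:
    """Combined enrichment score c = ln(p) * z.

    Positive when the term is simultaneously more significant (ln p < 0) and
    better-ranked than its permutation expectation (z < 0).
    """
    if not (0.0 < p <= 1.0):
        raise ParameterError("p must lie in (0, 1]")
    return math.log(p) * z


@dataclass(frozen=True)
class EnrichmentRecord:
    """Term-level enrichment: Fisher p, rank deviation z, combined score."""

    term: str
    overlap_genes: frozenset[str]
    p: float
    rank: float
    z: float
    combined: float
    p_adjusted: float | None = None

    def __post_init__(self) -> None:
        if abs(self.combined - math.log(self.p) * self.z) > 1e-9:
            raise ParameterError(
                f"{self.term}: combined score inconsistent with p and z"
            )


def enrich(
    library: GeneSetLibrary,
    module_genes: Iterable[str],
    universe: Iterable[str],
    n_permutations: int = 100,
    seed: int = 0,
    bh_across_terms: bool = False,
) -> list[EnrichmentRecord]:
    """Score every library term against one module; sorted by combined score.

    Raw Fisher p-values are reported by default (matching how enrichment
    services print them next to the combined score); ``bh_across_terms`` adds
    BH-adjusted p-values across the library's terms.
    """
    universe = frozenset(universe)
    module = frozenset(module_genes)
    ranks_z = rank_zscore(
        library, module, universe, n_permutations=n_permutations, seed=seed
    )
    pvals = {
        t: fisher_pvalue(module, library[t], universe) for t in library.terms
    }
    padj: Mapping[str, float] = {}
    if bh_across_terms:
        adj = bh_adjust([pvals[t] for t in library.terms])
        padj = dict(zip(library.terms, adj))
    records = []
    for t in library.terms:
        rank, z = ranks_z[t]
        records.append(
            EnrichmentRecord(
                term=t,
                overlap_genes=frozenset(module & library[t]),
                p=pvals[t],
                rank=rank,
                z=z,
                combined=combined_score(pvals[t], z),
                p_adjusted=padj.get(t) if bh_across_terms else None,
            )
        )
    return sorted(records, key=lambda r: (-r.combined, r.p, r.term))


def write_enrichment(
    records: Sequence[EnrichmentRecord],
    path: str | Path,
    module_ids: Sequence[int] | None = None,
) -> None:
    """TSV output: term, p, z, combined score and the semicolon-joined overlap."""
    lines = [
        "module\tterm\tp\tz\tcombined_score\toverlap_size\toverlap_genes"
    ]
    module_ids = module_ids or [0] * len(records)
    for mid, r in zip(module_ids, records):
        lines.append(
            "\t".join(
                [
                    str(mid),
                    r.term,
                    f"{r.p:.6g}",
                    f"{r.z:.6g}",
                    f"{r.combined:.6g}",
                    str(len(r.overlap_genes)),
                    ";".join(sorted(r.overlap_genes)),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", newline="\n")
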