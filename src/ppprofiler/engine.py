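"""The partial-profiling engine.

For one gene, the engine descends the gene's deduplicated homolog list and
maintains a partial profile: after j distinct profile taxa have been
encountered, h_j of them carry bit 1 in the query profile. At each depth it
evaluates the upper binomial tail

    p_j = P(X >= h_j),  X ~ Binomial(j, p)

i.e. the probability of seeing at least h_j positives among j draws when
positives occur with prior probability p. The gene's score is
-log10(p*) with p* = min_j p_j: the depth where the growing family agrees
most significantly with the profile. Tails are computed in log space via
the regularized incomplete beta (scipy's binomial log-survival function);
printed scores routinely exceed 100, far below linear-space resolution.

A read-ahead bound makes the scan safely prunable: from state (j, h) the
best reachable tail assumes every not-yet-seen positive taxon arrives
next. Once that bound cannot beat the incumbent minimum the scan stops,
with results guaranteed identical to the exhaustive walk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from scipy.stats import binom

from .hitlists import HitList, collapse_hitlist
from .profiles import Profile, ProfileError, collapse_profile
from .taxonomy import TaxonomyTree

_LN10 = math.log(10.0)


def log10_binom_tail(h: int, j: int, p: float) -> float:
    """log10 of the upper binomial tail P(X >= h), X ~ Binomial(j, p)."""
    if not (0.0 < p < 1.0):
        raise ValueError(f"p must lie strictly in (0, 1), got {p}")
    if h < 0 or j < 0 or h > j:
        raise ValueError(f"need 0 <= h <= j, got h={h}, j={j}")
    if h == 0:
        return 0.0
    return float(binom.logsf(h - 1, j, p)) / _LN10


def binom_tail(h: int, j: int, p: float) -> float:
    """Upper binomial tail P(X >= h) = sum_{k=h}^{j} C(j,k) p^k (1-p)^(j-k)."""
    return 10.0 ** log10_binom_tail(h, j, p)


class BoundTable:
    """Best-case tail probabilities for the read-ahead pruning bound.

    From state (j, h) with r = |T1| - h positive taxa still unseen, the
    most favourable continuation meets all r of them immediately, giving
    tail P(X >= h + r) at j + r trials. That value can only rise as more
    mismatches are absorbed, so it is an admissible stopping bound.
    """

    def __init__(self, n_positive: int, prior: float):
        if not (0.0 < prior < 1.0):
            raise ValueError(f"prior must lie strictly in (0, 1), got {prior}")
        self.n_positive = n_positive
        self.prior = prior
        self._cache: dict[tuple[int, int], float] = {}

    def log10_bound(self, j: int, h: int) -> float:
        key = (j, h)
        if key not in self._cache:
            r = max(self.n_positive - h, 0)
            self._cache[key] = log10_binom_tail(h + r, j + r, self.prior)
        return self._cache[key]

    def bound(self, j: int, h: int) -> float:
        return 10.0 ** self.log10_bound(j, h)


def make_bound_table(profile: Profile, prior: float | None = None,
                     max_depth: int | None = None) -> BoundTable:
    """Precompute the pruning bound for a profile (``max_depth`` is accepted
    for interface symmetry; bounds are cached lazily per state)."""
    p = prior if prior is not None else profile.prior
    return BoundTable(len(profile.t1), p)


@dataclass
class GeneScore:
    """The optimized result for one gene.

    ``score`` is -log10(p*), kept at full precision internally and
    rounded to 2 dp only in text output. ``last_true_sig`` is the
    significance of the deepest in-optimum hit whose taxon is positive;
    ``first_false_sig`` that of the next profile taxon beyond the optimum
    (necessarily a mismatch), or None when the list is exhausted.
    """

    gene_id: str
    log10_p_star: float
    j_star: int
    h_star: int
    last_true_sig: float | None = None
    first_false_sig: float | None = None

    @property
    def score(self) -> float:
        return -self.log10_p_star

    @property
    def p_star(self) -> float:
        return 10.0 ** self.log10_p_star

    def rank_key(self):
        return (-self.score, self.gene_id)


@dataclass
class PPPResult:
    """Genome-wide ranking: GeneScores sorted by score descending, ties
    broken by gene id, plus run metadata (profile sizes, prior, rank
    level, skipped-hit counters, pruning statistics)."""

    scores: list[GeneScore] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.scores)

    def __iter__(self):
        return iter(self.scores)

    def gene(self, gene_id: str) -> GeneScore:
        for gs in self.scores:
            if gs.gene_id == gene_id:
                return gs
        raise KeyError(gene_id)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for key, value in sorted(self.metadata.items()):
                fh.write(f"# {key}: {value}\n")
            fh.write("# columns: gene_id\tscore\tp_star\tj_star\th_star"
                     "\tlast_true_sig\tfirst_false_sig\n")
            for gs in self.scores:
                lt = _fmt_sig(gs.last_true_sig)
                ff = _fmt_sig(gs.first_false_sig)
                fh.write(
                    f"{gs.gene_id}\t{gs.score:.2f}\t{gs.p_star:.6g}"
                    f"\t{gs.j_star}\t{gs.h_star}\t{lt}\t{ff}\n"
                )


def _fmt_sig(sig: float | None) -> str:
    return "(none)" if sig is None else f"{sig:.6g}"


def _effective_prior(profile: Profile, prior_override: float | None) -> float:
    p = prior_override if prior_override is not None else profile.prior
    if not (0.0 < p < 1.0):
        raise ProfileError(
            f"degenerate prior {p}: the binomial model needs p strictly in "
            "(0, 1); override it or adjust the profile"
        )
    return p


def score_gene(
    hl: HitList,
    profile: Profile,
    prior_override: float | None = None,
    bound: BoundTable | None = None,
    max_depth: int | None = None,
) -> GeneScore:
    """Scan one hit list and return the depth of best profile agreement.

    Hits whose taxon is absent from the profile are invisible: they
    advance neither j nor h. Ties in p* go to the smallest j (the
    smallest family consistent with the best score). A gene with no
    profile-taxon hits scores 0 at j* = h* = 0.
    """
    p = _effective_prior(profile, prior_override)
    best_lp = 0.0
    best_j = 0
    best_h = 0
    j = 0
    h = 0
    seq: list[tuple[float, int]] = []  # (significance, bit) per profile taxon
    pruned = False
    for i, hit in enumerate(hl.hits):
        bit = profile.bit(hit.taxon)
        if bit is None:
            continue
        j += 1
        h += bit
        seq.append((hl.significance(hit), bit))
        if max_depth is not None and j > max_depth:
            seq.pop()
            break
        if bit:  # p_j can only reach a new minimum right after a match
            lp = log10_binom_tail(h, j, p)
            if lp < best_lp:
                best_lp, best_j, best_h = lp, j, h
        if bound is not None and bound.log10_bound(j, h) >= best_lp:
            pruned = True
            if len(seq) == best_j:
                # read ahead one profile taxon so the flanking significance
                # beyond the optimum matches the exhaustive scan
                for later in hl.hits[i + 1:]:
                    lbit = profile.bit(later.taxon)
                    if lbit is not None:
                        seq.append((hl.significance(later), lbit))
                        break
            break

    last_true = None
    for sig, bit in seq[:best_j]:
        if bit:
            last_true = sig
    first_false = seq[best_j][0] if len(seq) > best_j else None
    gs = GeneScore(hl.query_id, best_lp, best_j, best_h, last_true, first_false)
    gs.pruned = pruned
    return gs


def score_genome(
    hitlists: Mapping[str, HitList],
    profile: Profile,
    prior_override: float | None = None,
    rank: str | None = None,
    tree: TaxonomyTree | None = None,
    early_stop: bool = True,
    max_depth: int | None = None,
) -> PPPResult:
    """Score every gene of a genome against the query profile and rank.

    With ``rank`` set, hit-list taxa and the profile are collapsed to that
    taxonomic level first (a collapsed node is positive when any
    constituent is). The read-ahead bound is an exact optimization: its
    results are identical to the exhaustive scan.
    """
    if rank is not None and tree is None:
        raise ValueError("rank collapsing requires a taxonomy tree")
    work_profile = profile
    if rank is not None:
        work_profile = collapse_profile(profile, tree, rank)
    p = _effective_prior(work_profile, prior_override)
    bound = BoundTable(len(work_profile.t1), p) if early_stop else None

    scores = []
    n_pruned = 0
    for gene_id in sorted(hitlists):
        hl = hitlists[gene_id]
        if rank is not None:
            hl = collapse_hitlist(hl, tree, rank)
        gs = score_gene(hl, work_profile, prior_override=p, bound=bound,
                        max_depth=max_depth)
        n_pruned += getattr(gs, "pruned", False)
        scores.append(gs)
    scores.sort(key=GeneScore.rank_key)
    meta = {
        "n_genes": len(scores),
        "n_positive": len(work_profile.t1),
        "n_negative": len(work_profile.t0),
        "prior": p,
        "rank": rank or "(none)",
        "early_stopped_genes": n_pruned if early_stop else 0,
    }
    return PPPResult(scores, meta)


@dataclass
class HmmCutoffResult:
    """A GeneScore for an HMM hits list plus the suggested score cutoff.

    ``score_at_optimum`` is the full-sequence bit score of the hit that
    completed the optimal depth; ``cutoff`` is the midpoint between that
    hit and the next hit in the raw list (or the boundary score itself
    when the list ends there), a ready-made family inclusion threshold.
    """

    gene_score: GeneScore
    score_at_optimum: float | None
    cutoff: float | None


def optimal_hmm_cutoff(
    hl: HitList,
    profile: Profile,
    prior_override: float | None = None,
) -> HmmCutoffResult:
    """Find the optimal depth in a bit-score-ordered HMM hits list and the
    score threshold separating the implied family from the rest."""
    gs = score_gene(hl, profile, prior_override=prior_override)
    if gs.j_star == 0:
        return HmmCutoffResult(gs, None, None)
    j = 0
    boundary_idx = None
    for i, hit in enumerate(hl.hits):
        if profile.bit(hit.taxon) is not None:
            j += 1
            if j == gs.j_star:
                boundary_idx = i
                break
    assert boundary_idx is not None
    at_opt = hl.hits[boundary_idx].bitscore
    if boundary_idx + 1 < len(hl.hits):
        cutoff = (at_opt + hl.hits[boundary_idx + 1].bitscore) / 2.0
    else:
        cutoff = at_opt
    return HmmCutoffResult(gs, at_opt, cutoff)
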