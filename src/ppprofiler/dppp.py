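"""Double partial profiling: depth sweeps from a single seed protein.

When one protein of an uncharacterized multi-component system is known,
the right size for its protein family — and hence the right query profile
— is not. The sweep walks down the seed protein's deduplicated homolog
list, and at sampled depths d builds a query profile marking the first d
distinct taxa positive (prior d / |universe|). Each profile is scored
against the whole target genome with the partial-profiling engine, and
every gene keeps its best score over all sampled depths. If the seed truly
belongs to a system, the depth closest to the system's real carrier set
produces the best profile, and the other members surface at that depth.

The seed protein itself always matches its own depth-d profile perfectly
(h = j = d), so its own score d * log10(|universe| / d) rises with depth;
it is reported but carries no information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .engine import PPPResult, score_genome
from .hitlists import HitList
from .profiles import Profile


@dataclass
class AggregatedGene:
    gene_id: str
    best_score: float
    best_depth: int
    profile_size_at_best: int
    j_star: int
    h_star: int

    def rank_key(self):
        return (-self.best_score, self.gene_id)


@dataclass
class DepthSweepResult:
    """Aggregated sweep output.

    ``aggregated`` is sorted by best score descending; each entry records
    the smallest depth achieving that score. ``trajectories`` holds the
    per-depth score series for the top-K aggregated genes (for
    score-versus-depth plots); ``per_depth`` maps each sampled depth to
    (profile size, full ranking at that depth).
    """

    query_id: str
    depths: list[int] = field(default_factory=list)
    aggregated: list[AggregatedGene] = field(default_factory=list)
    trajectories: dict[str, list[tuple[int, float]]] = field(default_factory=dict)
    per_depth: dict[int, tuple[int, PPPResult]] = field(default_factory=dict)

    def gene(self, gene_id: str) -> AggregatedGene:
        for ag in self.aggregated:
            if ag.gene_id == gene_id:
                return ag
        raise KeyError(gene_id)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# query: {self.query_id}\n")
            fh.write(f"# depths: {','.join(map(str, self.depths))}\n")
            fh.write("# columns: gene_id\tbest_score\tbest_depth"
                     "\tprofile_size_at_best\tj_star\th_star\n")
            for ag in self.aggregated:
                fh.write(
                    f"{ag.gene_id}\t{ag.best_score:.2f}\t{ag.best_depth}"
                    f"\t{ag.profile_size_at_best}\t{ag.j_star}\t{ag.h_star}\n"
                )


def profiles_from_depths(
    query_hl: HitList,
    universe: set[int],
    depths: list[int],
) -> list[Profile]:
    """Build one query profile per sampled depth of the seed's hit list.

    The profile at depth d marks the first d distinct taxa of the list as
    positive and every other universe taxon negative; its prior is
    d / |universe|. Depths beyond the list length are clipped with a
    warning.
    """
    taxa = query_hl.taxa()
    out = []
    for d in depths:
        if d > len(taxa):
            warnings.warn(
                f"depth {d} exceeds hit-list length {len(taxa)}; clipped"
            )
            d = len(taxa)
        positive = set(taxa[:d])
        entries = {t: (1 if t in positive else 0) for t in universe | positive}
        prior = d / len(universe)
        out.append(Profile(entries, prior_override=prior if 0 < prior < 1 else None))
    return out


def dppp_sweep(
    query_hl: HitList,
    genome_hitlists: Mapping[str, HitList],
    universe: set[int],
    stride: int = 10,
    min_depth: int = 10,
    max_depth: int | None = None,
    prior_override: float | None = None,
    top_k: int = 10,
) -> DepthSweepResult:
    """Run the engine at every sampled depth and aggregate best scores.

    Per gene the maximum score over depths is kept, ties going to the
    smallest depth. ``prior_override`` replaces the naive d/|universe|
    prior at every depth when given.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    n = len(query_hl)
    if n == 0:
        raise ValueError("empty query hit list")
    top = min(max_depth, n) if max_depth is not None else n
    lo = min(min_depth, top)
    depths = list(range(lo, top + 1, stride))
    if not depths:
        depths = [top]

    result = DepthSweepResult(query_id=query_hl.query_id, depths=depths)
    profiles = profiles_from_depths(query_hl, universe, depths)
    best: dict[str, AggregatedGene] = {}
    series: dict[str, list[tuple[int, float]]] = {}
    for d, prof in zip(depths, profiles):
        ppp = score_genome(genome_hitlists, prof, prior_override=prior_override)
        result.per_depth[d] = (len(prof.t1), ppp)
        for gs in ppp:
            series.setdefault(gs.gene_id, []).append((d, gs.score))
            cur = best.get(gs.gene_id)
            if cur is None or gs.score > cur.best_score:
                best[gs.gene_id] = AggregatedGene(
                    gs.gene_id, gs.score, d, len(prof.t1), gs.j_star, gs.h_star
                )
    result.aggregated = sorted(best.values(), key=AggregatedGene.rank_key)
    result.trajectories = {
        ag.gene_id: series[ag.gene_id] for ag in result.aggregated[:top_k]
    }
    return result
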