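import math

import numpy as np
import pytest

from ppprofiler import (
    HitList,
    HitRecord,
    Profile,
    SyntheticSpec,
    generate,
    load_taxdump,
    parse_blast_tab,
    read_id2tax,
    read_profile,
    read_universe,
)

TOY_NODES = (
    "1\t|\t1\t|\tno rank\t|\n"
    "2\t|\t1\t|\tsuperkingdom\t|\n"
    "9\t|\t2\t|\tgenus\t|\n"
    "101\t|\t9\t|\tspecies\t|\n"
    "102\t|\t9\t|\tspecies\t|\n"
    "103\t|\t2\t|\tspecies\t|\n"
)

TOY_NAMES = (
    "1\t|\troot\t|\t\t|\tscientific name\t|\n"
    "2\t|\tBacteria\t|\t\t|\tscientific name\t|\n"
    "9\t|\tGenus9\t|\t\t|\tscientific name\t|\n"
    "101\t|\tSp 101\t|\t\t|\tscientific name\t|\n"
    "102\t|\tSp 102\t|\t\t|\tscientific name\t|\n"
    "103\t|\tSp 103\t|\t\t|\tscientific name\t|\n"
)


@pytest.fixture(scope="session")
def toy_taxdump(tmp_path_factory):
    d = tmp_path_factory.mktemp("taxdump")
    (d / "nodes.dmp").write_text(TOY_NODES)
    (d / "names.dmp").write_text(TOY_NAMES)
    return d


@pytest.fixture(scope="session")
def toy_tree(toy_taxdump):
    return load_taxdump(toy_taxdump / "nodes.dmp", toy_taxdump / "names.dmp")


@pytest.fixture(scope="session")
def dataset(tmp_path_factory):
    """Default study conditions: 100 genomes, one 10-member system in 15
    carriers, no leakage or contamination, 40 background families."""
    return generate(SyntheticSpec(seed=1), tmp_path_factory.mktemp("ds"))


@pytest.fixture(scope="session")
def parsed(dataset):
    id2tax = read_id2tax(dataset.id2tax_path)
    lists, unmapped = parse_blast_tab(dataset.blast_path, id2tax)
    return {
        "id2tax": id2tax,
        "lists": lists,
        "unmapped": unmapped,
        "universe": read_universe(dataset.universe_path),
        "profile": read_profile(dataset.profile_paths["sys0"]),
        "members": set(dataset.truth["systems"]["sys0"]["members"]),
        "carriers": set(dataset.truth["systems"]["sys0"]["carriers"]),
    }


# ---------------------------------------------------------------- oracles


def tail_sum(h: int, j: int, p: float) -> float:
    """Explicit binomial tail summation, independent of the engine path."""
    return math.fsum(
        math.comb(j, k) * p**k * (1 - p) ** (j - k) for k in range(h, j + 1)
    )


def brute_force_optimum(hl: HitList, profile: Profile, p: float):
    """Exhaustive scan over every depth with summed tails; smallest j wins
    ties. Returns (p_star, j_star, h_star)."""
    j = h = 0
    best = (1.0, 0, 0)
    for hit in hl.hits:
        bit = profile.bit(hit.taxon)
        if bit is None:
            continue
        j += 1
        h += bit
        pj = tail_sum(h, j, p)
        if pj < best[0] * (1 - 1e-12):
            best = (pj, j, h)
    return best


def random_hitlist(rng: np.random.Generator, query_id: str, taxa: list[int],
                   n_hits: int) -> HitList:
    chosen = rng.choice(taxa, size=min(n_hits, len(taxa)), replace=False)
    hits = [
        HitRecord(query_id, f"{query_id}.s{i}", int(t),
                  float(10.0 ** rng.uniform(-80, 1)), float(rng.uniform(30, 500)))
        for i, t in enumerate(chosen)
    ]
    return HitList(query_id, hits, "evalue").normalized()


def random_profile(rng: np.random.Generator, taxa: list[int],
                   frac: float = 0.3) -> Profile:
    bits = rng.random(len(taxa)) < frac
    entries = {int(t): int(b) for t, b in zip(taxa, bits)}
    if not any(entries.values()):
        entries[taxa[0]] = 1
    if all(entries.values()):
        entries[taxa[-1]] = 0
    return Profile(entries)
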