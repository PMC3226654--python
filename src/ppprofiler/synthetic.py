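"""Desk-scale synthetic datasets in the tool's external formats.

The generator emits a complete, internally consistent mini-study with no
download: a taxdump-style taxonomy (genera over genome-level leaves), a
BLAST tabular file for every gene of one target genome, a HMMER3 tblout
for one planted family, a sequence-id -> taxid mapping, carrier profiles,
and a ground-truth table. Planted "systems" are cohorts of member genes
co-occurring in the same carrier genomes, the signal partial profiling is
meant to recover; background families with arbitrary taxon frequencies
supply the null, and optional paralog pairs reproduce the
homology-contamination effect where a relative of a true member inherits
part of its signal.

Significance synthesis models the essential feature of real ranked hit
lists: within-family hits draw E-values from a strong band
(1e-120 .. 1e-20 by default) and cross-family noise from a weak band
(1e-8 .. 10), so after per-taxon deduplication every member's carrier taxa
precede all non-carrier taxa. Contaminating hits (non-carriers spuriously
gaining a member) are placed at the geometric midpoint of the family band:
a moderate-similarity recruit that lands inside the family boundary, which
is what produces the off-by-one agreement patterns seen with raw hit
lists. Paralog cross-hits occupy an intermediate band between family and
noise. Sequence-level simulation is deliberately out of scope; the
significance values themselves are the model.

Runs are seeded and byte-reproducible.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .engine import PPPResult
from .dppp import DepthSweepResult


@dataclass
class PlantedSystem:
    """One co-occurring gene cohort: ``n_members`` genes present in a
    ``carrier_fraction`` share of genomes; ``leakage_rate`` of carriers
    miss one member (a lost gene or missed gene call), and
    ``contamination_rate`` of non-carriers gain one (a spurious hit)."""

    n_members: int = 10
    carrier_fraction: float = 0.15
    leakage_rate: float = 0.0
    contamination_rate: float = 0.0


@dataclass
class SyntheticSpec:
    n_genomes: int = 100
    n_genera: int = 20
    planted_systems: list[PlantedSystem] = field(
        default_factory=lambda: [PlantedSystem()]
    )
    n_background_families: int = 40
    background_freq: tuple[float, float] = (0.05, 0.9)
    paralog_pairs: int = 0
    n_noise_hits: int = 25
    member_evalue_band: tuple[float, float] = (1e-120, 1e-20)
    paralog_evalue_band: tuple[float, float] = (1e-18, 1e-10)
    noise_evalue_band: tuple[float, float] = (1e-8, 10.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_genomes < 4:
            raise ValueError("need at least 4 genomes")
        for s in self.planted_systems:
            for frac in (s.carrier_fraction, s.leakage_rate, s.contamination_rate):
                if not (0.0 <= frac <= 1.0):
                    raise ValueError(f"fraction {frac} outside [0, 1]")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticSpec":
        with open(path) as fh:
            raw = json.load(fh)
        systems = [PlantedSystem(**s) for s in raw.pop("planted_systems", [])]
        spec = cls(**{k: tuple(v) if isinstance(v, list) else v
                      for k, v in raw.items()})
        if systems:
            spec.planted_systems = systems
        return spec


@dataclass
class SyntheticDataset:
    outdir: Path
    nodes_path: Path
    names_path: Path
    blast_path: Path
    id2tax_path: Path
    universe_path: Path
    profile_paths: dict[str, Path]
    tblout_path: Path | None
    target_taxid: int
    genomes: list[int]
    truth: dict


def _loguniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(10.0 ** rng.uniform(math.log10(lo), math.log10(hi)))


def _bitscore(evalue: float) -> float:
    return round(max(25.0, -2.0 * math.log10(max(evalue, 1e-300)) + 40.0), 1)


def _blast_row(q: str, s: str, evalue: float, bits: float) -> str:
    return (f"{q}\t{s}\t45.00\t200\t0\t0\t1\t200\t1\t200"
            f"\t{evalue:.3e}\t{bits:.1f}\n")


def write_tblout(path: str | Path, query_name: str,
                 rows: list[tuple[str, float, float]]) -> None:
    """Emit a minimal HMMER3 ``--tblout`` file.

    ``rows`` are (target_name, evalue, full_sequence_score), written in the
    given order with the standard 18-field layout plus description.
    """
    with open(path, "w") as fh:
        fh.write("# target name        accession  query name           "
                 "accession    E-value  score  bias   E-value  score  bias"
                 "   exp reg clu  ov env dom rep inc description of target\n")
        fh.write("#" + "-" * 19 + " " + "-" * 10 + " " + "-" * 20 + " "
                 + "-" * 10 + " " + "-" * 70 + "\n")
        for name, evalue, score in rows:
            fh.write(f"{name:<20} -          {query_name:<20} -          "
                     f"{evalue:9.2e} {score:6.1f}   0.0 {evalue:9.2e} "
                     f"{score:6.1f}   0.0   1.0   1   0   0   1   1   1   1 "
                     f"synthetic target\n")


def generate(spec: SyntheticSpec, outdir: str | Path) -> SyntheticDataset:
    """Write the full synthetic dataset under ``outdir`` and return its
    manifest plus ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    genomes = [1001 + i for i in range(spec.n_genomes)]
    target = genomes[0]
    genus_of = {t: 101 + (i % spec.n_genera) for i, t in enumerate(genomes)}

    taxdir = outdir / "taxdump"
    taxdir.mkdir(exist_ok=True)
    nodes_path = taxdir / "nodes.dmp"
    names_path = taxdir / "names.dmp"
    with open(nodes_path, "w") as fh:
        fh.write("1\t|\t1\t|\tno rank\t|\n")
        for g in sorted(set(genus_of.values())):
            fh.write(f"{g}\t|\t1\t|\tgenus\t|\n")
        for t in genomes:
            fh.write(f"{t}\t|\t{genus_of[t]}\t|\tspecies\t|\n")
    with open(names_path, "w") as fh:
        fh.write("1\t|\troot\t|\t\t|\tscientific name\t|\n")
        for g in sorted(set(genus_of.values())):
            fh.write(f"{g}\t|\tGenus{g}\t|\t\t|\tscientific name\t|\n")
        for t in genomes:
            fh.write(f"{t}\t|\tSpecies {t}\t|\t\t|\tscientific name\t|\n")

    # ---- family layout: which taxa carry which family -------------------
    families: dict[str, list[int]] = {}   # family id -> sorted present taxa
    truth_systems: dict[str, dict] = {}
    cross_hits: dict[str, str] = {}       # family -> paralog family

    for si, system in enumerate(spec.planted_systems):
        n_carriers = max(2, round(system.carrier_fraction * spec.n_genomes))
        others = rng.choice(genomes[1:], size=n_carriers - 1, replace=False)
        carriers = sorted([target] + [int(t) for t in others])
        members = []
        for mi in range(system.n_members):
            fam = f"sys{si}m{mi}"
            present = set(carriers)
            lose = [t for t in carriers if t != target]
            n_leak = round(system.leakage_rate * len(carriers))
            if n_leak:
                drop = rng.choice(lose, size=min(n_leak, len(lose)), replace=False)
                present -= {int(t) for t in drop}
            non_carriers = [t for t in genomes if t not in set(carriers)]
            n_contam = round(system.contamination_rate * len(non_carriers))
            if n_contam:
                gain = rng.choice(non_carriers, size=n_contam, replace=False)
                present |= {int(t) for t in gain}
            families[fam] = sorted(present)
            members.append(f"{fam}@{target}")
        truth_systems[f"sys{si}"] = {"carriers": carriers, "members": members}

    for k in range(spec.n_background_families):
        freq = rng.uniform(*spec.background_freq)
        n_present = max(2, round(freq * spec.n_genomes))
        others = rng.choice(genomes[1:], size=n_present - 1, replace=False)
        families[f"bg{k}"] = sorted([target] + [int(t) for t in others])

    for k in range(spec.paralog_pairs):
        # a family homologous to the k-th member of the first system: its
        # hit list will bleed into the member's carriers at paralog-band
        # E-values, the way ThiH inherits signal from HydG
        freq = rng.uniform(*spec.background_freq)
        n_present = max(2, round(freq * spec.n_genomes))
        others = rng.choice(genomes[1:], size=n_present - 1, replace=False)
        fam = f"par{k}"
        families[fam] = sorted([target] + [int(t) for t in others])
        partner = f"sys0m{k % spec.planted_systems[0].n_members}"
        cross_hits[fam] = partner

    # ---- id -> taxon mapping --------------------------------------------
    id2tax: dict[str, int] = {}
    for fam, present in families.items():
        for t in present:
            id2tax[f"{fam}@{t}"] = t

    # ---- per-gene BLAST rows --------------------------------------------
    blast_path = outdir / f"blast_{target}.tsv"
    contaminated_truth: dict[str, list[int]] = {}
    mid_band = math.sqrt(spec.member_evalue_band[0] * spec.member_evalue_band[1])
    with open(blast_path, "w") as fh:
        for fam in sorted(families):
            present = families[fam]
            gene = f"{fam}@{target}"
            rows: list[tuple[float, str, float]] = [(1e-180, gene, 800.0)]
            carrier_set = None
            if fam.startswith("sys"):
                carrier_set = set(truth_systems[fam.split("m")[0]]["carriers"])
            for t in present:
                if t == target:
                    continue
                if carrier_set is not None and t not in carrier_set:
                    ev = mid_band  # contaminating recruit, mid-family band
                    contaminated_truth.setdefault(gene, []).append(t)
                else:
                    ev = _loguniform(rng, *spec.member_evalue_band)
                rows.append((ev, f"{fam}@{t}", _bitscore(ev)))
            if fam in cross_hits:
                partner = cross_hits[fam]
                for t in families[partner]:
                    if t in set(present):
                        continue
                    ev = _loguniform(rng, *spec.paralog_evalue_band)
                    rows.append((ev, f"{partner}@{t}", _bitscore(ev)))
            # leaked carriers stay out of a member's noise: leakage models a
            # genome where the gene is truly absent
            excluded = set(present) | (carrier_set or set())
            noise_pool = [t for t in genomes if t not in excluded]
            n_noise = min(spec.n_noise_hits, len(noise_pool))
            if n_noise:
                for t in rng.choice(noise_pool, size=n_noise, replace=False):
                    ev = _loguniform(rng, *spec.noise_evalue_band)
                    sid = f"{fam}.n@{int(t)}"
                    id2tax[sid] = int(t)
                    rows.append((ev, sid, _bitscore(ev)))
            rows.sort(key=lambda r: (r[0], r[1]))
            for ev, sid, bits in rows:
                fh.write(_blast_row(gene, sid, ev, bits))

    id2tax_path = outdir / "id2tax.tsv"
    with open(id2tax_path, "w") as fh:
        for sid in sorted(id2tax):
            fh.write(f"{sid}\t{id2tax[sid]}\n")

    universe_path = outdir / "universe.tsv"
    with open(universe_path, "w") as fh:
        for t in genomes:
            fh.write(f"{t}\n")

    # ---- carrier profiles ------------------------------------------------
    profile_paths: dict[str, Path] = {}
    for sname, info in truth_systems.items():
        ppath = outdir / f"profile_{sname}.tsv"
        carriers = set(info["carriers"])
        with open(ppath, "w") as fh:
            for t in genomes:
                fh.write(f"{t}\t{1 if t in carriers else 0}\n")
        profile_paths[sname] = ppath

    # ---- tblout for the first planted member ----------------------------
    tblout_path = None
    if truth_systems:
        first = truth_systems["sys0"]["members"][0]
        fam = first.split("@")[0]
        tbl_rows = []
        for t in families[fam]:
            ev = 1e-180 if t == target else _loguniform(rng, *spec.member_evalue_band)
            tbl_rows.append((f"{fam}@{t}", ev, _bitscore(ev)))
        tbl_rows.sort(key=lambda r: (-r[2], r[0]))
        tblout_path = outdir / f"{fam}.tblout"
        write_tblout(tblout_path, fam, tbl_rows)

    truth = {
        "target_taxid": target,
        "genomes": genomes,
        "systems": truth_systems,
        "families": {fam: taxa for fam, taxa in sorted(families.items())},
        "contaminated_members": contaminated_truth,
        "spec": {**asdict(spec),
                 "planted_systems": [asdict(s) for s in spec.planted_systems]},
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")

    return SyntheticDataset(
        outdir=outdir,
        nodes_path=nodes_path,
        names_path=names_path,
        blast_path=blast_path,
        id2tax_path=id2tax_path,
        universe_path=universe_path,
        profile_paths=profile_paths,
        tblout_path=tblout_path,
        target_taxid=target,
        genomes=genomes,
        truth=truth,
    )


def truth_eval(
    result: PPPResult | DepthSweepResult,
    members: set[str],
    k: int,
) -> tuple[float, dict[str, int]]:
    """Precision-at-k against planted membership, plus each member's rank.

    Returns ``(precision, ranks)`` where ranks are 1-based positions in
    the result ordering. k = 0 is vacuously precision 1.0 (warned);
    k beyond the result length is clipped.
    """
    if isinstance(result, DepthSweepResult):
        ordered = [ag.gene_id for ag in result.aggregated]
    else:
        ordered = [gs.gene_id for gs in result.scores]
    if k == 0:
        warnings.warn("precision-at-0 is vacuously 1.0")
        return 1.0, {}
    if k > len(ordered):
        k = len(ordered)
    hits = sum(1 for g in ordered[:k] if g in members)
    ranks = {g: i + 1 for i, g in enumerate(ordered) if g in members}
    return hits / k, ranks


def read_universe(path: str | Path) -> set[int]:
    """One taxid per line (comments/blanks ignored)."""
    out: set[int] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(int(line))
    return out
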