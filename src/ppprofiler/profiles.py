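"""Binary taxonomic query profiles and their algebra.

A profile assigns each taxon in its domain a bit: 1 if the genome carries
the query trait (positive set T1), 0 if it does not (negative set T0). The
binomial prior p defaults to |T1| / (|T1| + |T0|) and may be overridden to
any value strictly inside (0, 1); raising it increases the penalty each
profile mismatch pays during scoring, which favours rare "only-if"
families, while lowering it favours supersets of the profile.

Taxa absent from a profile are invisible to scoring: they neither match nor
mismatch. Masking a taxon removes it from the domain entirely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .taxonomy import TaxonomyTree, ancestor_at_rank, descendants

BOOLEAN_OPS = ("and", "or", "xor", "diff")


class ProfileError(ValueError):
    pass


@dataclass
class Profile:
    """Map taxid -> bit, with a binomial prior.

    ``prior_override``, when set, replaces the relative-frequency default
    and must lie strictly in (0, 1).
    """

    entries: dict[int, int] = field(default_factory=dict)
    prior_override: float | None = None

    def __post_init__(self) -> None:
        for t, b in self.entries.items():
            if b not in (0, 1):
                raise ProfileError(f"bit for taxid {t} must be 0 or 1, got {b!r}")
        if self.prior_override is not None:
            _check_prior(self.prior_override)

    @property
    def t1(self) -> set[int]:
        return {t for t, b in self.entries.items() if b == 1}

    @property
    def t0(self) -> set[int]:
        return {t for t, b in self.entries.items() if b == 0}

    @property
    def prior(self) -> float:
        if self.prior_override is not None:
            return self.prior_override
        if not self.entries:
            return 0.0
        return len(self.t1) / len(self.entries)

    @property
    def scoreable(self) -> bool:
        """The binomial model degenerates at p in {0, 1}."""
        return 0.0 < self.prior < 1.0

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Profile):
            return NotImplemented
        return self.entries == other.entries

    def bit(self, taxid: int) -> int | None:
        return self.entries.get(taxid)

    def with_prior(self, prior: float | None) -> "Profile":
        return Profile(dict(self.entries), prior_override=prior)


def _check_prior(p: float) -> None:
    if not (0.0 < p < 1.0):
        raise ProfileError(f"prior must lie strictly in (0, 1), got {p}")


def read_profile(path: str | Path) -> Profile:
    """Read the two-column TSV dialect: taxid <TAB> 0|1.

    '#' comment lines and blank lines are ignored. Duplicate taxids with
    the same bit collapse with a warning; conflicting bits are an error.
    """
    entries: dict[int, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ProfileError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(fields)}"
                )
            try:
                taxid = int(fields[0])
            except ValueError:
                raise ProfileError(f"{path}:{lineno}: bad taxid {fields[0]!r}") from None
            if fields[1] not in ("0", "1"):
                raise ProfileError(
                    f"{path}:{lineno}: bit must be 0 or 1, got {fields[1]!r}"
                )
            bit = int(fields[1])
            if taxid in entries:
                if entries[taxid] != bit:
                    raise ProfileError(
                        f"{path}:{lineno}: taxid {taxid} listed with conflicting bits"
                    )
                warnings.warn(f"{path}:{lineno}: duplicate entry for taxid {taxid}")
            entries[taxid] = bit
    return Profile(entries)


def write_profile(profile: Profile, path: str | Path) -> None:
    """Emit the two-column TSV dialect, taxids in ascending order."""
    with open(path, "w") as fh:
        for taxid in sorted(profile.entries):
            fh.write(f"{taxid}\t{profile.entries[taxid]}\n")


def profile_from_hits(
    hit_ids: Iterable[str],
    id2tax: Mapping[str, int],
    universe: set[int],
) -> tuple[Profile, int]:
    """Profile from a collection of sequence identifiers.

    Universe taxa hit by at least one mapped id get bit 1; the rest get 0.
    Returns ``(profile, n_unmapped)`` where the count covers hit ids with
    no taxon mapping (reported, never fatal).
    """
    if not universe:
        raise ProfileError("universe must be non-empty")
    unmapped = 0
    positive: set[int] = set()
    for hid in hit_ids:
        tax = id2tax.get(hid)
        if tax is None:
            unmapped += 1
        elif tax in universe:
            positive.add(tax)
    entries = {t: (1 if t in positive else 0) for t in universe}
    return Profile(entries), unmapped


def profile_from_taxon(tree: TaxonomyTree, taxid: int, universe: set[int]) -> Profile:
    """Profile marking universe members inside the ``taxid`` lineage as 1."""
    inside = descendants(tree, taxid) | {taxid}
    return Profile({t: (1 if t in inside else 0) for t in universe})


def combine(a: Profile, b: Profile, op: str) -> Profile:
    """Bitwise combination over the union of the two taxon domains.

    A taxon absent from one operand contributes bit 0 there. ``diff`` is
    ``a AND NOT b``; the other ops are symmetric.
    """
    if op not in BOOLEAN_OPS:
        raise ProfileError(f"unknown op {op!r}; expected one of {BOOLEAN_OPS}")
    entries: dict[int, int] = {}
    for taxid in set(a.entries) | set(b.entries):
        x = a.entries.get(taxid, 0)
        y = b.entries.get(taxid, 0)
        if op == "and":
            entries[taxid] = x & y
        elif op == "or":
            entries[taxid] = x | y
        elif op == "xor":
            entries[taxid] = x ^ y
        else:  # diff
            entries[taxid] = x & (1 - y)
    return Profile(entries)


def mask(profile: Profile, taxa: set[int]) -> Profile:
    """Drop the listed taxa from the profile domain entirely.

    Masked genomes neither match nor mismatch during scoring; the default
    prior is recomputed from the survivors. Masking absent taxa is a no-op.
    """
    return Profile(
        {t: b for t, b in profile.entries.items() if t not in taxa},
        prior_override=profile.prior_override,
    )


def collapse_profile(profile: Profile, tree: TaxonomyTree, rank: str) -> Profile:
    """Collapse the profile domain to ancestors at ``rank``.

    A collapsed node's bit is 1 if any constituent taxon has bit 1, so
    positives stay detectable after strain-level structure is folded away.
    """
    entries: dict[int, int] = {}
    for taxid, bit in profile.entries.items():
        anc = ancestor_at_rank(tree, taxid, rank) if taxid in tree else taxid
        entries[anc] = entries.get(anc, 0) | bit
    return Profile(entries, prior_override=profile.prior_override)
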