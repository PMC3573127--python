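"""Data model and I/O for mitochondrial HVR-I haplotypes.

Haplotypes are represented as sets of variant sites relative to the revised
Cambridge Reference Sequence (rCRS) over the hypervariable-region-I window
np 16056-16409.  The motif shorthand used throughout the ancient-DNA
literature drops the leading 16000 from positions and encodes substitution
type in letter case: ``129c-189C-362C`` means a transversion to C at 16129
and transitions to C at 16189 and 16362.  Parenthesised tokens such as
``(390R)`` carry an IUPAC ambiguity code and are excluded from all
population-genetic comparisons.

The module also houses the packaged genotypes of the three ancient North
East European sites (the Mesolithic Yuzhnyy Oleni Ostrov and Popovo
graveyards, pooled as ``aUzPo``, and the Early Metal Age Bol'shoy Oleni
Ostrov site, ``aBOO``), haplogroup assignment against an editable motif
table, and HVR-I versus coding-region haplogroup consistency checks.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "HVR1_START",
    "HVR1_END",
    "MOTIF_OFFSET",
    "MotifParseError",
    "VariantSite",
    "HvrHaplotype",
    "AncientIndividual",
    "PopulationSample",
    "MotifTable",
    "parse_motif",
    "format_motif",
    "load_motif_table",
    "assign_haplogroup",
    "check_hg_consistency",
    "load_ancient_fixture",
    "ancient_population",
    "reference_window",
    "read_haplotype_table",
    "write_haplotype_table",
    "write_fasta",
    "read_fasta",
]

HVR1_START = 16056
HVR1_END = 16409
MOTIF_OFFSET = 16000

_IUPAC_AMBIGUOUS = set("RYSWKMBDHVN")
_TRANSITIONS = {frozenset("AG"), frozenset("CT")}

SITE_GROUPS = {"aUz": "aUzPo", "aPo": "aUzPo", "aBOO": "aBOO"}
"""Burial sites and the statistical pool each belongs to."""


class MotifParseError(ValueError):
    """Raised when a motif string or haplotype table row is malformed."""


@dataclass(frozen=True, order=True)
class VariantSite:
    """A single variant relative to the rCRS within the sequenced window.

    ``kind`` records substitution type as printed (upper case = transition,
    lower case = transversion); ``ambiguous`` marks IUPAC-coded sites that
    are excluded from all comparisons.
    """

    position: int
    derived_base: str
    kind: str = "transition"
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if not HVR1_START <= self.position <= HVR1_END:
            raise MotifParseError(
                f"position {self.position} outside sequenced window "
                f"[{HVR1_START}, {HVR1_END}]"
            )
        base = self.derived_base.upper()
        object.__setattr__(self, "derived_base", base)
        if self.ambiguous:
            if base not in _IUPAC_AMBIGUOUS:
                raise MotifParseError(
                    f"ambiguous site {self.position} carries non-IUPAC code {base!r}"
                )
        elif base not in "ACGT":
            raise MotifParseError(
                f"resolved site {self.position} carries base {base!r}; "
                "IUPAC codes must be parenthesised"
            )
        if self.kind not in ("transition", "transversion"):
            raise MotifParseError(f"unknown substitution kind {self.kind!r}")


@dataclass(frozen=True)
class HvrHaplotype:
    """A set of HVR-I variant sites over a sequenced window.

    Equality and matching consider only resolved (unambiguous) variants over
    the intersection of the two sequenced windows, mirroring how exclusion
    of heteroplasmic/ambiguous positions is handled in downstream analyses.
    """

    variants: frozenset[VariantSite]
    range_start: int = HVR1_START
    range_end: int = HVR1_END

    def __post_init__(self) -> None:
        positions = [v.position for v in self.variants]
        if len(positions) != len(set(positions)):
            raise MotifParseError("duplicate variant positions in haplotype")
        for v in self.variants:
            if not self.range_start <= v.position <= self.range_end:
                raise MotifParseError(
                    f"variant at {v.position} outside window "
                    f"[{self.range_start}, {self.range_end}]"
                )

    @property
    def resolved(self) -> frozenset[tuple[int, str]]:
        """(position, base) pairs of the unambiguous variants."""
        return frozenset(
            (v.position, v.derived_base) for v in self.variants if not v.ambiguous
        )

    def matches(self, other: "HvrHaplotype") -> bool:
        """Exact-match comparison over the window intersection.

        A motif is read as a complete observation over its window, so the
        absence of a listed variant is informative: ``356C`` does not match
        ``093C-356C`` when both windows cover np 16093.
        """
        lo = max(self.range_start, other.range_start)
        hi = min(self.range_end, other.range_end)
        mine = {pv for pv in self.resolved if lo <= pv[0] <= hi}
        theirs = {pv for pv in other.resolved if lo <= pv[0] <= hi}
        return mine == theirs

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HvrHaplotype):
            return NotImplemented
        return self.matches(other)

    def __hash__(self) -> int:
        return hash(self.resolved)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"HvrHaplotype({format_motif(self) or 'rCRS'})"


_TOKEN_RE = re.compile(r"^(?P<paren>\()?(?P<pos>\d+)(?P<base>[A-Za-z])(?(paren)\))$")


def parse_motif(
    motif: str,
    offset: int = MOTIF_OFFSET,
    range_start: int = HVR1_START,
    range_end: int = HVR1_END,
) -> HvrHaplotype:
    """Parse a dash-separated motif string into an :class:`HvrHaplotype`.

    The empty string denotes an rCRS-identical sequence over the window.
    """
    variants: list[VariantSite] = []
    seen: set[int] = set()
    motif = motif.strip()
    if motif:
        for token in motif.split("-"):
            m = _TOKEN_RE.match(token)
            if m is None:
                raise MotifParseError(f"malformed motif token {token!r}")
            position = offset + int(m.group("pos"))
            letter = m.group("base")
            ambiguous = m.group("paren") is not None
            kind = "transition" if letter.isupper() else "transversion"
            if position in seen:
                raise MotifParseError(f"duplicate position in token {token!r}")
            seen.add(position)
            try:
                variants.append(
                    VariantSite(position, letter.upper(), kind, ambiguous)
                )
            except MotifParseError as exc:
                raise MotifParseError(f"token {token!r}: {exc}") from None
    return HvrHaplotype(frozenset(variants), range_start, range_end)


def format_motif(hap: HvrHaplotype, offset: int = MOTIF_OFFSET) -> str:
    """Format a haplotype back to motif shorthand (inverse of parse)."""
    tokens = []
    for v in sorted(hap.variants):
        letter = v.derived_base if v.kind == "transition" else v.derived_base.lower()
        if v.ambiguous:
            letter = v.derived_base  # IUPAC codes are printed upper-case
        token = f"{v.position - offset:03d}{letter}"
        if v.ambiguous:
            token = f"({token})"
        tokens.append(token)
    return "-".join(tokens)


@dataclass(frozen=True)
class AncientIndividual:
    """One ancient genotype: haplotype plus both haplogroup assignments."""

    sample_id: str
    site: str
    haplotype: HvrHaplotype
    hg_hvr: str
    hg_coding: str

    @property
    def pool(self) -> str:
        return SITE_GROUPS[self.site]


@dataclass
class PopulationSample:
    """A labelled collection of (haplotype, haplogroup) records.

    ``age_generations`` is the sampling age (0 for modern populations);
    ``sites`` optionally records the burial site of each member, used by
    kinship-robust redundancy filtering.
    """

    label: str
    members: list[tuple[HvrHaplotype, str]]
    age_generations: float = 0.0
    sites: list[str] | None = None

    def __post_init__(self) -> None:
        if self.age_generations < 0:
            raise ValueError("age_generations must be non-negative")
        if self.sites is not None and len(self.sites) != len(self.members):
            raise ValueError("sites must parallel members")

    @property
    def n(self) -> int:
        return len(self.members)

    @property
    def haplotypes(self) -> list[HvrHaplotype]:
        return [h for h, _ in self.members]


# ---------------------------------------------------------------------------
# Haplogroup assignment
# ---------------------------------------------------------------------------


class MotifTable:
    """Ordered haplogroup-diagnostic motif definitions.

    Entries are ordered most-derived-first; assignment returns the first
    haplogroup whose full diagnostic variant set is contained in the
    haplotype's resolved variants.  ``coding_class`` maps HVR-I labels to the
    haplogroup-level class resolvable from the coding-region SNP assay.
    """

    def __init__(
        self,
        entries: Sequence[tuple[str, frozenset[tuple[int, str]]]],
        coding_class: Mapping[str, str],
    ) -> None:
        if not entries:
            raise ValueError("empty haplogroup motif table")
        self.entries = list(entries)
        self.coding_class = dict(coding_class)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MotifTable":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        entries = []
        for item in raw["motifs"]:
            variants = frozenset(
                (int(v[:-1]), v[-1].upper()) for v in item.get("variants", [])
            )
            entries.append((str(item["label"]), variants))
        return cls(entries, raw.get("coding_class", {}))

    @property
    def fallback(self) -> str | None:
        for label, motif in self.entries:
            if not motif:
                return label
        return None

    def assign(self, hap: HvrHaplotype, fallback: str | None = None) -> str:
        resolved = hap.resolved
        for label, motif in self.entries:
            if motif and motif <= resolved:
                return label
        fb = fallback if fallback is not None else self.fallback
        if fb is None:
            raise ValueError("no haplogroup matched and no fallback configured")
        return fb


def _data_path(name: str) -> Path:
    return Path(resources.files("paleomt.data").joinpath(name))  # type: ignore[arg-type]


_DEFAULT_TABLE: MotifTable | None = None


def load_motif_table(path: str | Path | None = None) -> MotifTable:
    """Load a motif table; the packaged default when ``path`` is omitted."""
    global _DEFAULT_TABLE
    if path is not None:
        return MotifTable.from_yaml(path)
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = MotifTable.from_yaml(_data_path("hg_motifs.yaml"))
    return _DEFAULT_TABLE


def assign_haplogroup(
    hap: HvrHaplotype,
    motif_table: MotifTable | None = None,
    fallback: str | None = None,
) -> str:
    """Assign the most-derived haplogroup whose motif the haplotype carries."""
    table = motif_table if motif_table is not None else load_motif_table()
    return table.assign(hap, fallback=fallback)


def check_hg_consistency(
    hg_hvr: str,
    hg_coding: str,
    mapping: Mapping[str, str] | None = None,
) -> bool:
    """True iff the HVR-I haplogroup rolls up to the coding-level class."""
    if mapping is None:
        mapping = load_motif_table().coding_class
    if hg_hvr not in mapping:
        raise KeyError(f"haplogroup {hg_hvr!r} absent from HVR-to-coding mapping")
    return mapping[hg_hvr] == hg_coding


# ---------------------------------------------------------------------------
# Packaged ancient fixture
# ---------------------------------------------------------------------------

POOL_AGES = {"aUzPo": 300.0, "aBOO": 140.0}


def load_ancient_fixture(
    site_filter: Iterable[str] | None = None,
) -> list[AncientIndividual]:
    """Load the 34 packaged ancient genotypes, optionally filtered by site."""
    if site_filter is not None:
        site_filter = set(site_filter)
        unknown = site_filter - set(SITE_GROUPS)
        if unknown:
            raise ValueError(f"unknown site label(s): {sorted(unknown)}")
    individuals = []
    with open(_data_path("ancient_hvr1.csv"), newline="") as fh:
        for row in csv.DictReader(fh):
            if site_filter is not None and row["site"] not in site_filter:
                continue
            individuals.append(
                AncientIndividual(
                    sample_id=row["sample_id"],
                    site=row["site"],
                    haplotype=parse_motif(row["motif"]),
                    hg_hvr=row["hg_hvr"],
                    hg_coding=row["hg_coding"],
                )
            )
    return individuals


def ancient_population(pool: str) -> PopulationSample:
    """The pooled ancient population sample ``aUzPo`` or ``aBOO``."""
    if pool not in POOL_AGES:
        raise ValueError(f"unknown pool {pool!r}; expected one of {sorted(POOL_AGES)}")
    sites = [s for s, g in SITE_GROUPS.items() if g == pool]
    inds = load_ancient_fixture(site_filter=sites)
    return PopulationSample(
        label=pool,
        members=[(ind.haplotype, ind.hg_hvr) for ind in inds],
        age_generations=POOL_AGES[pool],
        sites=[ind.site for ind in inds],
    )


# ---------------------------------------------------------------------------
# CSV / FASTA plumbing
# ---------------------------------------------------------------------------

CSV_COLUMNS = ["sample_id", "population", "age_generations", "motif", "hg"]

_REFERENCE: str | None = None


def reference_window() -> str:
    """The packaged 354-nt reference window (synthetic rCRS stand-in)."""
    global _REFERENCE
    if _REFERENCE is None:
        lines = _data_path("synthetic_rcrs_hvr1.fasta").read_text().splitlines()
        _REFERENCE = "".join(l.strip() for l in lines if not l.startswith(">"))
        assert len(_REFERENCE) == HVR1_END - HVR1_START + 1
    return _REFERENCE


def read_haplotype_table(path: str | Path) -> list[PopulationSample]:
    """Read population samples from the documented CSV schema.

    Columns: sample_id, population, age_generations, motif, hg.  Rows are
    grouped into one :class:`PopulationSample` per population label; schema
    violations raise errors naming the offending row.
    """
    groups: dict[str, PopulationSample] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(CSV_COLUMNS) - set(reader.fieldnames):
            raise MotifParseError(
                f"haplotype table must have columns {CSV_COLUMNS}, "
                f"got {reader.fieldnames}"
            )
        for i, row in enumerate(reader, start=2):
            try:
                hap = parse_motif(row["motif"])
                age = float(row["age_generations"])
            except (MotifParseError, ValueError) as exc:
                raise MotifParseError(f"row {i}: {exc}") from None
            label = row["population"]
            pop = groups.get(label)
            if pop is None:
                pop = groups[label] = PopulationSample(label, [], age)
            elif pop.age_generations != age:
                raise MotifParseError(
                    f"row {i}: population {label!r} has inconsistent ages"
                )
            pop.members.append((hap, row["hg"]))
    return list(groups.values())


def write_haplotype_table(
    populations: Iterable[PopulationSample], path: str | Path
) -> None:
    """Write population samples in the documented CSV schema."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for pop in populations:
            for i, (hap, hg) in enumerate(pop.members):
                writer.writerow(
                    [
                        f"{pop.label}-{i + 1}",
                        pop.label,
                        f"{pop.age_generations:g}",
                        format_motif(hap),
                        hg,
                    ]
                )


def _apply_variants(hap: HvrHaplotype) -> str:
    seq = list(reference_window())
    for v in hap.variants:
        seq[v.position - HVR1_START] = v.derived_base
    return "".join(seq)


def write_fasta(pop: PopulationSample, path: str | Path) -> None:
    """Write full 354-nt window sequences reconstructed from the reference."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(
            Seq(_apply_variants(hap)),
            id=f"{pop.label}-{i + 1}",
            description=f"hg={hg} age={pop.age_generations:g}",
        )
        for i, (hap, hg) in enumerate(pop.members)
    ]
    seqio_write(records, str(path), "fasta")


def _classify_substitution(ref: str, alt: str) -> tuple[str, bool]:
    if alt not in "ACGT":
        return "transition", True
    kind = "transition" if frozenset((ref, alt)) in _TRANSITIONS else "transversion"
    return kind, False


def read_fasta(path: str | Path, label: str = "fasta") -> PopulationSample:
    """Read window sequences and express them as variant sets vs the reference."""
    from Bio.SeqIO import parse as seqio_parse

    ref = reference_window()
    members: list[tuple[HvrHaplotype, str]] = []
    for record in seqio_parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        if len(seq) != len(ref):
            raise MotifParseError(
                f"record {record.id}: length {len(seq)} != window {len(ref)}"
            )
        variants = []
        for i, (r, a) in enumerate(zip(ref, seq)):
            if r != a:
                kind, ambiguous = _classify_substitution(r, a)
                variants.append(VariantSite(HVR1_START + i, a, kind, ambiguous))
        members.append((HvrHaplotype(frozenset(variants)), ""))
    return PopulationSample(label, members)
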