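"""HMMER per-domain output parsing and ABC functional-unit calling.

The pipeline identifies ABC transporters from Pfam profile hits on chain
sequences: ``hmmsearch --domtblout`` tables are parsed, hits are filtered
(per-domain independent E-value <= 0.001 and HMM-span coverage >= 90% of the
profile length), categorized as nucleotide-binding-domain (NBD) or
transmembrane-domain (TMD) matches through a profile catalog, and an
assembly is called a functional ABC unit when its chains together carry at
least two NBD hits and at least one TMD hit.  Assemblies with two NBD hits
and no TMD hit are routed to manual review — they may carry a novel
transmembrane fold that no current profile matches.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, TextIO

from abcconform.errors import AbcConformError, DomtbloutFormatError
from abcconform.structure_io import Residue, ResidueLabel, Structure

__all__ = [
    "PfamHit",
    "ProfileCatalog",
    "UnitCall",
    "MappedRange",
    "parse_domtblout",
    "render_domtblout",
    "filter_hits",
    "categorize_hits",
    "call_functional_unit",
    "map_hit_to_structure",
    "load_default_catalog",
]

# HMMER3 domtblout columns (hmmsearch orientation: target = sequence,
# query = profile).  Indices into the whitespace-split row.
_COL_TARGET = 0
_COL_TLEN = 2
_COL_QUERY_NAME = 3
_COL_QUERY_ACC = 4
_COL_QLEN = 5
_COL_FULL_EVALUE = 6
_COL_FULL_SCORE = 7
_COL_DOM_N = 9
_COL_DOM_OF = 10
_COL_C_EVALUE = 11
_COL_I_EVALUE = 12
_COL_DOM_SCORE = 13
_COL_HMM_FROM = 15
_COL_HMM_TO = 16
_COL_ALI_FROM = 17
_COL_ALI_TO = 18
_COL_ENV_FROM = 19
_COL_ENV_TO = 20
_N_COLUMNS = 23  # columns before the free-text description


@dataclass
class PfamHit:
    """One profile-domain match on one chain sequence."""

    target_name: str
    profile_name: str
    profile_accession: str
    profile_length: int
    full_seq_evalue: float
    domain_ievalue: float
    hmm_from: int
    hmm_to: int
    ali_from: int
    ali_to: int
    target_length: int = 0
    category: str | None = None  # "NBD" | "TMD" | "other", set by categorize_hits
    class_hint: str | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.hmm_from <= self.hmm_to <= self.profile_length):
            raise ValueError(
                f"{self.target_name}/{self.profile_name}: invalid hmm span "
                f"{self.hmm_from}-{self.hmm_to} of {self.profile_length}"
            )
        if self.ali_from > self.ali_to:
            raise ValueError("ali_from must be <= ali_to")
        if self.full_seq_evalue < 0 or self.domain_ievalue < 0:
            raise ValueError("E-values must be non-negative")

    @property
    def hmm_span(self) -> int:
        return self.hmm_to - self.hmm_from + 1

    @property
    def profile_coverage(self) -> float:
        return self.hmm_span / self.profile_length


def parse_domtblout(source: str | Path | TextIO | Iterable[str]) -> list[PfamHit]:
    """Parse HMMER3 ``--domtblout`` text into :class:`PfamHit` records.

    Accepts a path, an open text stream, or an iterable of lines.  Comment
    (``#``) and blank lines are ignored; a data row with fewer than the 23
    fixed columns raises :class:`DomtbloutFormatError` citing the line.
    """
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        lines: Iterable[str] = Path(source).read_text().splitlines()
    elif isinstance(source, str):
        lines = source.splitlines()
    elif isinstance(source, io.TextIOBase):
        lines = source.read().splitlines()
    else:
        lines = [str(line).rstrip("\n") for line in source]

    hits: list[PfamHit] = []
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        fields = stripped.split()
        if len(fields) < _N_COLUMNS:
            raise DomtbloutFormatError(
                f"expected >= {_N_COLUMNS} columns, found {len(fields)}",
                line_number=lineno,
            )
        try:
            hit = PfamHit(
                target_name=fields[_COL_TARGET],
                profile_name=fields[_COL_QUERY_NAME],
                profile_accession=fields[_COL_QUERY_ACC],
                profile_length=int(fields[_COL_QLEN]),
                full_seq_evalue=float(fields[_COL_FULL_EVALUE]),
                domain_ievalue=float(fields[_COL_I_EVALUE]),
                hmm_from=int(fields[_COL_HMM_FROM]),
                hmm_to=int(fields[_COL_HMM_TO]),
                ali_from=int(fields[_COL_ALI_FROM]),
                ali_to=int(fields[_COL_ALI_TO]),
                target_length=int(fields[_COL_TLEN]),
            )
        except ValueError as exc:
            raise DomtbloutFormatError(str(exc), line_number=lineno) from exc
        hits.append(hit)
    return hits


def render_domtblout(hits: Iterable[PfamHit]) -> str:
    """Render hits as HMMER3 ``--domtblout`` text (inverse of the parser).

    Only the fields the pipeline models carry information; the remaining
    mandatory columns are filled with neutral values.
    """
    out = [
        "#                                                               --- full sequence --- -------------- this domain -------------   hmm coord   ali coord   env coord",
        "# target name        accession   tlen query name           accession   qlen   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to  from    to  from    to  acc description of target",
        "#------------------- ---------- ----- -------------------- ---------- ----- --------- ------ ----- --- --- --------- --------- ------ ----- ----- ----- ----- ----- ----- ----- ---- ---------------------",
    ]
    grouped: dict[tuple[str, str], list[PfamHit]] = {}
    for hit in hits:
        grouped.setdefault((hit.target_name, hit.profile_name), []).append(hit)
    for (_, _), group in grouped.items():
        for k, hit in enumerate(group, start=1):
            tlen = hit.target_length or hit.ali_to
            out.append(
                f"{hit.target_name:<20} -          {tlen:>5} "
                f"{hit.profile_name:<20} {hit.profile_accession:<10} "
                f"{hit.profile_length:>5} {hit.full_seq_evalue:>9.3g} "
                f"{100.0:>6.1f} {0.0:>5.1f} {k:>3} {len(group):>3} "
                f"{hit.domain_ievalue:>9.3g} {hit.domain_ievalue:>9.3g} "
                f"{90.0:>6.1f} {0.0:>5.1f} "
                f"{hit.hmm_from:>5} {hit.hmm_to:>5} "
                f"{hit.ali_from:>5} {hit.ali_to:>5} "
                f"{hit.ali_from:>5} {hit.ali_to:>5} 0.95 -"
            )
    return "\n".join(out) + "\n"


def filter_hits(
    hits: Iterable[PfamHit],
    max_evalue: float = 0.001,
    min_profile_coverage: float = 0.90,
) -> list[PfamHit]:
    """Apply the domain-hit acceptance rules.

    A hit is retained iff its per-domain independent E-value is at most
    ``max_evalue`` (default 0.001) and its HMM span covers at least
    ``min_profile_coverage`` (default 90%) of the profile length.  Order is
    preserved and the operation is idempotent.
    """
    return [
        h
        for h in hits
        if h.domain_ievalue <= max_evalue
        and h.hmm_span >= min_profile_coverage * h.profile_length
    ]


@dataclass
class CatalogEntry:
    accession: str
    name: str
    clan: str
    category: str  # "NBD" | "TMD" | "other"
    class_hint: str | None = None

    def __post_init__(self) -> None:
        if self.category not in ("NBD", "TMD", "other"):
            raise ValueError(f"bad category {self.category!r}")
        if self.class_hint is not None and self.category != "TMD":
            raise ValueError("class_hint only allowed for TMD profiles")


class ProfileCatalog:
    """Pfam accession -> NBD/TMD category and structural-class hint.

    Lookups try the (version-stripped) accession first and fall back to the
    profile name, so synthetic profiles without real accessions resolve too.
    """

    def __init__(self, entries: Iterable[CatalogEntry]):
        self._by_acc: dict[str, CatalogEntry] = {}
        self._by_name: dict[str, CatalogEntry] = {}
        for e in entries:
            self._by_acc[self._strip(e.accession)] = e
            self._by_name[e.name] = e
        if not self._by_acc:
            raise AbcConformError("empty profile catalog")

    @staticmethod
    def _strip(accession: str) -> str:
        return accession.split(".")[0]

    def __len__(self) -> int:
        return len(self._by_acc)

    def lookup(self, accession: str, name: str | None = None) -> CatalogEntry | None:
        entry = self._by_acc.get(self._strip(accession))
        if entry is None and name is not None:
            entry = self._by_name.get(name)
        return entry

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ProfileCatalog":
        entries = []
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise AbcConformError(f"catalog line {lineno}: need >= 4 columns")
            acc, name, clan, category = parts[:4]
            hint = parts[4] if len(parts) > 4 and parts[4] else None
            entries.append(CatalogEntry(acc, name, clan, category, hint))
        return cls(entries)


def load_default_catalog() -> ProfileCatalog:
    """Load the ABC Pfam profile catalog shipped with the package."""
    path = resources.files("abcconform").joinpath("data/profile_catalog.tsv")
    with resources.as_file(path) as p:
        return ProfileCatalog.from_tsv(p)


def categorize_hits(
    hits: Iterable[PfamHit], catalog: ProfileCatalog
) -> tuple[list[PfamHit], list[PfamHit]]:
    """Annotate hits with NBD/TMD category and structural-class hint.

    Returns ``(annotated, uncataloged)``; hits whose accession (and name)
    are absent from the catalog are collected rather than silently dropped.
    """
    annotated: list[PfamHit] = []
    uncataloged: list[PfamHit] = []
    for hit in hits:
        entry = catalog.lookup(hit.profile_accession, hit.profile_name)
        if entry is None:
            uncataloged.append(hit)
            continue
        annotated.append(replace(hit, category=entry.category, class_hint=entry.class_hint))
    return annotated, uncataloged


@dataclass
class UnitCall:
    """Functional-unit verdict for one assembly."""

    entry_id: str
    n_nbd: int
    n_tmd: int
    verdict: str  # "functional" | "not_functional" | "needs_review"
    contributing_hits: list[PfamHit] = field(default_factory=list)


def _collapse_overlaps(hits: list[PfamHit]) -> list[PfamHit]:
    """Merge same-chain, same-category hits overlapping > 50% mutually.

    One physical domain often attracts several overlapping profile matches;
    only the best-E hit of each overlap cluster is counted.
    """
    kept: list[PfamHit] = []
    for hit in sorted(hits, key=lambda h: h.domain_ievalue):
        dup = False
        for other in kept:
            if hit.target_name != other.target_name or hit.category != other.category:
                continue
            lo = max(hit.ali_from, other.ali_from)
            hi = min(hit.ali_to, other.ali_to)
            overlap = max(0, hi - lo + 1)
            len_a = hit.ali_to - hit.ali_from + 1
            len_b = other.ali_to - other.ali_from + 1
            if overlap > 0.5 * len_a and overlap > 0.5 * len_b:
                dup = True
                break
        if not dup:
            kept.append(hit)
    return kept


def call_functional_unit(entry_id: str, hits: Iterable[PfamHit]) -> UnitCall:
    """Count NBD/TMD hits over all chains of one assembly and call the unit.

    ``functional`` requires >= 2 NBD and >= 1 TMD hits (a homodimer of a
    half transporter contributes each chain's hits); >= 2 NBD with no TMD is
    ``needs_review``; anything else is ``not_functional``.  Hits must
    already be filtered and categorized.
    """
    categorized = [h for h in hits if h.category in ("NBD", "TMD")]
    counted = _collapse_overlaps(categorized)
    n_nbd = sum(1 for h in counted if h.category == "NBD")
    n_tmd = sum(1 for h in counted if h.category == "TMD")
    if n_nbd >= 2 and n_tmd >= 1:
        verdict = "functional"
    elif n_nbd >= 2 and n_tmd == 0:
        verdict = "needs_review"
    else:
        verdict = "not_functional"
    return UnitCall(entry_id, n_nbd, n_tmd, verdict, contributing_hits=counted)


@dataclass
class MappedRange:
    """Structure residues covered by one sequence-coordinate hit."""

    labels: list[ResidueLabel]
    gap_count: int
    low_coverage: bool


def map_hit_to_structure(
    hit: PfamHit, structure: Structure, chain_id: str
) -> MappedRange:
    """Resolve a hit's [ali_from, ali_to] sequence span onto structure residues.

    Positions are matched through each residue's ``label_seq`` (1-based
    polymer position); unresolved positions are reported as a gap count, and
    a span resolved below 50% carries a low-coverage flag.
    """
    if chain_id not in structure.chains:
        raise AbcConformError(
            f"chain {chain_id!r} not in structure {structure.entry_id}"
        )
    span = range(hit.ali_from, hit.ali_to + 1)
    present: dict[int, Residue] = {}
    for res in structure.chains[chain_id]:
        if res.label_seq is not None:
            present[res.label_seq] = res
    labels = [
        present[pos].label(chain_id) for pos in span if pos in present
    ]
    gap_count = len(span) - len(labels)
    low = len(labels) < 0.5 * len(span)
    return MappedRange(labels=labels, gap_count=gap_count, low_coverage=low)
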