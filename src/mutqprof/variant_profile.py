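"""Cohort mutation profiling for a single protein.

This module turns per-sample mutation tables (HGVSp strings or raw coding
sequences) into classified :class:`MutationRecord` objects, applies them to a
reference protein, summarises the cohort (type, domain, truncation and
BLOSUM62-conservation breakdowns, per-position hotspots) and emits mutant
protein FASTA for downstream structure prediction.

Conventions
-----------
* Residue positions are 1-based inclusive everywhere.
* A premature stop is encoded as ``"*"`` in :attr:`MutationRecord.alt_aa`.
* A substitution is *conservative* iff its BLOSUM62 score is strictly
  positive — the standard convention, under which the archetypal Arg→His
  change (score 0) counts as non-conservative.
"""

from __future__ import annotations

import io
import re
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    AlphabetError,
    ClassificationError,
    ConsistencyError,
    FormatError,
    FrameError,
    RangeError,
    ResidueError,
)

__all__ = [
    "STOP",
    "STANDARD_AA",
    "MutationKind",
    "DomainInterval",
    "ReferenceProtein",
    "MutationRecord",
    "SubstitutionMatrix",
    "CohortSummary",
    "TP53_DOMAINS",
    "parse_hgvsp",
    "format_hgvsp",
    "translate_cds",
    "apply_mutation",
    "assign_domain",
    "classify_substitution",
    "blosum62",
    "summarize_cohort",
    "write_mutant_fasta",
    "record_from_sequences",
    "read_cohort_csv",
    "load_cohort_dir",
    "load_reference_fasta",
]

STOP = "*"
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

_THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Ter": STOP,
}
ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


class MutationKind(str, Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


class Domain(str, Enum):
    """Functional regions of the profiled protein (p53 nomenclature)."""

    TAD1 = "TAD1"
    TAD2 = "TAD2"
    PRR = "PRR"
    DBD = "DBD"
    OD = "OD"


INTER_DOMAIN = "inter-domain"
OUT_OF_RANGE = "out-of-range"


@dataclass(frozen=True)
class DomainInterval:
    """A named, 1-based inclusive residue interval."""

    name: Domain
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError(f"invalid interval {self.name}: {self.start}-{self.end}")

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end


#: TP53 domain map: TAD1/TAD2 transactivation domains, proline-rich region,
#: DNA-binding domain and oligomerisation (tetramerisation) domain. Residues
#: 293-322 and 357-393 fall between/after the named domains.
TP53_DOMAINS: tuple[DomainInterval, ...] = (
    DomainInterval(Domain.TAD1, 1, 40),
    DomainInterval(Domain.TAD2, 41, 61),
    DomainInterval(Domain.PRR, 62, 93),
    DomainInterval(Domain.DBD, 94, 292),
    DomainInterval(Domain.OD, 323, 356),
)

#: Canonical length of the full-length p53 protein.
TP53_CANONICAL_LENGTH = 393


@dataclass(frozen=True)
class ReferenceProtein:
    """A reference amino-acid sequence plus its domain map.

    ``sequence`` uses 1-based residue numbering throughout the package, so
    residue *i* is ``sequence[i - 1]``.
    """

    id: str
    sequence: str
    domains: tuple[DomainInterval, ...] = ()

    def __post_init__(self) -> None:
        bad = set(self.sequence) - set(STANDARD_AA)
        if bad:
            raise ResidueError(f"non-standard residues in reference: {sorted(bad)}")
        spans = sorted(self.domains, key=lambda d: d.start)
        for d in spans:
            if d.end > self.canonical_length:
                raise ValueError(f"domain {d.name} exceeds sequence length")
        for a, b in zip(spans, spans[1:]):
            if b.start <= a.end:
                raise ValueError(f"overlapping domains {a.name}/{b.name}")

    @property
    def canonical_length(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        if not 1 <= position <= self.canonical_length:
            raise RangeError(
                f"position {position} outside 1..{self.canonical_length}"
            )
        return self.sequence[position - 1]


@dataclass(frozen=True)
class MutationRecord:
    """One protein-level variant in one sample.

    ``position`` is ``None`` only for records that carry no usable residue
    coordinate (e.g. complex CDS-derived changes); such records always have
    ``kind == OTHER`` or ``SYNONYMOUS`` and are excluded from FASTA output.
    """

    sample_id: str
    raw: str
    ref_aa: str
    position: int | None
    alt_aa: str
    kind: MutationKind

    @property
    def variant_key(self) -> tuple[str, int, str]:
        if self.position is None:
            raise RangeError(f"record {self.raw!r} has no position")
        return (self.ref_aa, self.position, self.alt_aa)

    @property
    def label(self) -> str:
        """Short variant label, e.g. ``R157H`` or ``R196*``."""
        if self.position is None:
            return self.raw
        return f"{self.ref_aa}{self.position}{self.alt_aa}"


_HGVSP_RE = re.compile(
    r"^(?:p\.)?(?P<ref>[A-Za-z]{3}|[A-Z])(?P<pos>\d+)(?P<alt>[A-Za-z]{3}|[A-Z*=])$"
)


def _normalize_residue(token: str, *, allow_stop: bool) -> str:
    if len(token) == 1:
        if token in STANDARD_AA:
            return token
        if token == STOP and allow_stop:
            return STOP
        raise ResidueError(f"unknown residue code {token!r}")
    code = token.capitalize()
    if code in _THREE_TO_ONE:
        one = _THREE_TO_ONE[code]
        if one == STOP and not allow_stop:
            raise ResidueError(f"stop codon not allowed as reference ({token!r})")
        return one
    raise ResidueError(f"unknown residue code {token!r}")


def parse_hgvsp(raw: str, sample_id: str = "") -> MutationRecord:
    """Parse a protein-level variant string such as ``p.R157H``.

    Accepts one- or three-letter residue codes, an optional ``p.`` prefix,
    stops written as ``*`` or ``Ter``, and ``=`` for an explicitly synonymous
    change. Bare positions without an alternate allele (``R196``) are
    rejected: guessing the change would silently misclassify the record.
    """
    text = raw.strip()
    m = _HGVSP_RE.match(text)
    if m is None:
        raise FormatError(f"cannot parse HGVSp string {raw!r}")
    ref = _normalize_residue(m.group("ref"), allow_stop=False)
    position = int(m.group("pos"))
    if position < 1:
        raise FormatError(f"position must be >= 1 in {raw!r}")
    alt_token = m.group("alt")
    alt = ref if alt_token == "=" else _normalize_residue(alt_token, allow_stop=True)
    if alt == STOP:
        kind = MutationKind.NONSENSE
    elif alt == ref:
        kind = MutationKind.SYNONYMOUS
    else:
        kind = MutationKind.MISSENSE
    return MutationRecord(sample_id, raw, ref, position, alt, kind)


def format_hgvsp(record: MutationRecord, *, prefix: bool = True) -> str:
    """Render a record back to HGVSp short form (inverse of parse_hgvsp)."""
    if record.position is None:
        raise FormatError(f"record {record.raw!r} has no position to format")
    head = "p." if prefix else ""
    return f"{head}{record.ref_aa}{record.position}{record.alt_aa}"


def translate_cds(nucleotides: str) -> str:
    """Translate a coding DNA sequence with the standard genetic code.

    Translation stops at (and excludes) the first stop codon.
    """
    seq = nucleotides.strip().upper()
    if len(seq) % 3 != 0:
        raise FrameError(f"CDS length {len(seq)} is not a multiple of 3")
    bad = set(seq) - set("ACGT")
    if bad:
        raise AlphabetError(f"non-ACGT characters in CDS: {sorted(bad)}")
    return str(Seq(seq).translate(to_stop=True))


def apply_mutation(ref: ReferenceProtein, record: MutationRecord) -> str:
    """Apply one variant to the reference sequence.

    Missense substitutes one residue; nonsense truncates the protein to the
    ``position - 1`` prefix; synonymous returns the sequence unchanged.
    """
    if record.position is None or not 1 <= record.position <= ref.canonical_length:
        raise RangeError(
            f"position {record.position} outside canonical range "
            f"1..{ref.canonical_length}"
        )
    found = ref.sequence[record.position - 1]
    if found != record.ref_aa:
        raise ConsistencyError(
            f"reference mismatch at {record.position}: record says "
            f"{record.ref_aa}, reference has {found}"
        )
    if record.kind is MutationKind.NONSENSE:
        return ref.sequence[: record.position - 1]
    if record.kind is MutationKind.SYNONYMOUS:
        return ref.sequence
    return (
        ref.sequence[: record.position - 1]
        + record.alt_aa
        + ref.sequence[record.position :]
    )


def assign_domain(ref: ReferenceProtein, position: int) -> str:
    """Map a residue position to a domain name, "inter-domain" or "out-of-range".

    Total on positive integers: positions beyond the canonical length return
    ``"out-of-range"``; positions inside the protein but in no named domain
    return ``"inter-domain"``.
    """
    if position < 1:
        raise RangeError(f"position must be >= 1, got {position}")
    if position > ref.canonical_length:
        return OUT_OF_RANGE
    for interval in ref.domains:
        if position in interval:
            return interval.name.value
    return INTER_DOMAIN


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A symmetric amino-acid substitution scoring matrix."""

    name: str
    scores: Mapping[tuple[str, str], int]

    def score(self, a: str, b: str) -> int:
        return self.scores[(a, b)]


def blosum62() -> SubstitutionMatrix:
    """The BLOSUM62 log-odds matrix over the 20 standard residues."""
    arr = substitution_matrices.load("BLOSUM62")
    scores = {
        (a, b): int(arr[a, b]) for a in STANDARD_AA for b in STANDARD_AA
    }
    return SubstitutionMatrix("BLOSUM62", scores)


CONSERVATIVE = "conservative"
NON_CONSERVATIVE = "non_conservative"


def classify_substitution(matrix: SubstitutionMatrix, ref_aa: str, alt_aa: str) -> str:
    """Classify a missense substitution as conservative (score > 0) or not."""
    for aa in (ref_aa, alt_aa):
        if aa == STOP:
            raise ClassificationError(
                "stop gains are truncations, not scoreable substitutions"
            )
        if aa not in STANDARD_AA:
            raise ResidueError(f"unknown residue {aa!r}")
    return CONSERVATIVE if matrix.score(ref_aa, alt_aa) > 0 else NON_CONSERVATIVE


@dataclass
class CohortSummary:
    """Cohort-level mutation statistics.

    The counters satisfy three partition laws: ``missense + nonsense + other
    == total_records`` (where ``other`` covers synonymous and unclassifiable
    records); ``conservative_missense + non_conservative_missense ==
    missense``; and ``sum(per_domain) + inter_domain + out_of_canonical_range
    + unlocalized == total_records``. ``truncating == nonsense`` because only
    stop gains shorten the protein here.
    """

    total_records: int = 0
    unique_samples: int = 0
    unique_variants: int = 0
    missense: int = 0
    nonsense: int = 0
    other: int = 0
    per_domain: dict[str, int] = field(default_factory=dict)
    inter_domain: int = 0
    out_of_canonical_range: int = 0
    unlocalized: int = 0
    truncating: int = 0
    non_truncating: int = 0
    conservative_missense: int = 0
    non_conservative_missense: int = 0
    per_position_counts: dict[int, int] = field(default_factory=dict)

    def top_positions(self, n: int = 10) -> list[tuple[int, int]]:
        """Hotspot report: the n most recurrent positions (count-descending)."""
        return Counter(self.per_position_counts).most_common(n)

    def to_frame(self) -> pd.DataFrame:
        """Tabular summary with one metric per row."""
        rows = [
            ("Total mutation records", self.total_records),
            ("Unique samples with mutation", self.unique_samples),
            ("Unique HGVSp variants", self.unique_variants),
            ("Missense mutations", self.missense),
            ("Nonsense mutations", self.nonsense),
            ("Synonymous/other records", self.other),
        ]
        rows += [
            (f"Mutations in {name}", count)
            for name, count in self.per_domain.items()
        ]
        rows += [
            ("Mutations between domains", self.inter_domain),
            ("Mutations out of canonical range", self.out_of_canonical_range),
            ("Mutations without residue position", self.unlocalized),
            ("Non-truncating mutations", self.non_truncating),
            ("Truncating mutations", self.truncating),
            ("Conservative missense mutations", self.conservative_missense),
            ("Non-conservative missense mutations", self.non_conservative_missense),
        ]
        return pd.DataFrame(rows, columns=["metric", "value"])


def summarize_cohort(
    records: Sequence[MutationRecord],
    ref: ReferenceProtein,
    matrix: SubstitutionMatrix | None = None,
) -> CohortSummary:
    """Compute every cohort metric from a list of parsed records.

    An empty cohort yields the all-zero summary.
    """
    if matrix is None:
        matrix = blosum62()
    summary = CohortSummary(
        per_domain={d.name.value: 0 for d in ref.domains}
    )
    samples: set[str] = set()
    variants: set[tuple[str, int, str]] = set()
    positions: Counter[int] = Counter()

    for rec in records:
        summary.total_records += 1
        samples.add(rec.sample_id)
        if rec.kind is MutationKind.MISSENSE:
            summary.missense += 1
            label = classify_substitution(matrix, rec.ref_aa, rec.alt_aa)
            if label == CONSERVATIVE:
                summary.conservative_missense += 1
            else:
                summary.non_conservative_missense += 1
        elif rec.kind is MutationKind.NONSENSE:
            summary.nonsense += 1
            summary.truncating += 1
        else:
            summary.other += 1

        if rec.position is None:
            summary.unlocalized += 1
            continue
        variants.add(rec.variant_key)
        positions[rec.position] += 1
        where = assign_domain(ref, rec.position)
        if where == OUT_OF_RANGE:
            summary.out_of_canonical_range += 1
        elif where == INTER_DOMAIN:
            summary.inter_domain += 1
        else:
            summary.per_domain[where] += 1

    summary.unique_samples = len(samples)
    summary.unique_variants = len(variants)
    summary.non_truncating = summary.total_records - summary.truncating
    summary.per_position_counts = dict(positions)
    return summary


def write_mutant_fasta(
    ref: ReferenceProtein,
    records: Iterable[MutationRecord],
    *,
    skip_out_of_range: bool = True,
) -> tuple[str, pd.DataFrame]:
    """Emit one FASTA entry per unique applicable variant.

    Variants are deduplicated on (ref, position, alt) and written in
    deterministic order (position, then alternate residue); the 60-column
    wrapped entry header is ``>SAMPLE|LABEL`` with the first-seen sample id.
    Synonymous/other records never produce sequences. Returns the FASTA text
    and a manifest with one row per (sample, variant) pair, including skipped
    out-of-range records.
    """
    chosen: dict[tuple[str, int, str], MutationRecord] = {}
    manifest_rows: list[dict[str, object]] = []
    for rec in records:
        if rec.kind not in (MutationKind.MISSENSE, MutationKind.NONSENSE):
            continue
        if rec.position is None:
            continue
        out_of_range = rec.position > ref.canonical_length
        if out_of_range and not skip_out_of_range:
            raise RangeError(f"record {rec.label} out of canonical range")
        manifest_rows.append(
            {
                "sample_id": rec.sample_id,
                "variant": rec.label,
                "kind": rec.kind.value,
                "written": not out_of_range,
            }
        )
        if out_of_range:
            continue
        chosen.setdefault(rec.variant_key, rec)

    entries = []
    for key in sorted(chosen, key=lambda k: (k[1], k[2])):
        rec = chosen[key]
        seq = apply_mutation(ref, rec)
        entries.append(
            SeqRecord(Seq(seq), id=f"{rec.sample_id}|{rec.label}", description="")
        )
    buf = io.StringIO()
    SeqIO.write(entries, buf, "fasta")
    manifest = pd.DataFrame(
        manifest_rows, columns=["sample_id", "variant", "kind", "written"]
    )
    return buf.getvalue(), manifest


def record_from_sequences(
    ref: ReferenceProtein, mutant_seq: str, sample_id: str, raw: str = ""
) -> MutationRecord:
    """Infer a variant record by diffing a translated mutant against the reference.

    Recognises a single substitution (missense), a proper matching prefix
    (nonsense at the first missing residue) and identity (synonymous, no
    position). Anything else is classified ``other`` with no position.
    """
    wt = ref.sequence
    if mutant_seq == wt:
        return MutationRecord(sample_id, raw, "", None, "", MutationKind.SYNONYMOUS)
    if len(mutant_seq) == len(wt):
        diffs = [i for i, (a, b) in enumerate(zip(wt, mutant_seq)) if a != b]
        if len(diffs) == 1:
            i = diffs[0]
            return MutationRecord(
                sample_id, raw, wt[i], i + 1, mutant_seq[i], MutationKind.MISSENSE
            )
    elif len(mutant_seq) < len(wt) and wt.startswith(mutant_seq):
        pos = len(mutant_seq) + 1
        return MutationRecord(
            sample_id, raw, wt[pos - 1], pos, STOP, MutationKind.NONSENSE
        )
    return MutationRecord(sample_id, raw, "", None, "", MutationKind.OTHER)


def read_cohort_csv(
    source, reference: ReferenceProtein | None = None, *, sample_id: str | None = None
) -> list[MutationRecord]:
    """Read one per-sample mutation CSV.

    The dialect is auto-detected from the header: an ``hgvsp`` column holds
    protein-level variant strings; a ``cds_sequence`` column holds coding DNA
    which is translated and diffed against ``reference`` (required for that
    dialect). Rows that fail to parse become ``other`` records so the cohort
    total still counts them.
    """
    df = pd.read_csv(source, dtype=str, comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    records: list[MutationRecord] = []
    if "hgvsp" in df.columns:
        for _, row in df.iterrows():
            sid = str(row.get("sample_id", sample_id or ""))
            raw = str(row["hgvsp"])
            try:
                records.append(parse_hgvsp(raw, sid))
            except (FormatError, ResidueError):
                records.append(
                    MutationRecord(sid, raw, "", None, "", MutationKind.OTHER)
                )
    elif "cds_sequence" in df.columns:
        if reference is None:
            raise ConsistencyError("cds_sequence dialect requires a reference protein")
        for _, row in df.iterrows():
            sid = str(row.get("sample_id", sample_id or ""))
            raw = str(row["cds_sequence"])
            try:
                protein = translate_cds(raw)
            except (FrameError, AlphabetError):
                records.append(
                    MutationRecord(sid, raw, "", None, "", MutationKind.OTHER)
                )
                continue
            records.append(record_from_sequences(reference, protein, sid, raw))
    else:
        raise FormatError(
            "CSV must contain an 'hgvsp' or 'cds_sequence' column; "
            f"found {list(df.columns)}"
        )
    return records


def load_cohort_dir(
    directory: str | Path, reference: ReferenceProtein | None = None
) -> list[MutationRecord]:
    """Load every ``*.csv`` in a directory; each file is named after its sample."""
    records: list[MutationRecord] = []
    for path in sorted(Path(directory).glob("*.csv")):
        records.extend(read_cohort_csv(path, reference, sample_id=path.stem))
    return records


def load_reference_fasta(
    source, domains: tuple[DomainInterval, ...] = TP53_DOMAINS
) -> ReferenceProtein:
    """Read the first record of a protein FASTA as the reference."""
    rec = next(SeqIO.parse(source, "fasta"))
    return ReferenceProtein(rec.id, str(rec.seq), domains)
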