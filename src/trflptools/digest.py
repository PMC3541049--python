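"""In silico terminal restriction fragment (T-RF) prediction.

A T-RFLP fingerprint is read from the length of the fluorescently
end-labeled fragment produced when a PCR amplicon is cut by a restriction
enzyme.  With both primers labeled (different dyes) and three four-cutter
enzymes, each 16S phylotype is identified by a six-value signature:
three enzymes x two labeled ends.  This module predicts those signatures
from sequence: primer location (IUPAC-aware, mismatch-tolerant), first
recognition-site search on each strand, and the primer-inclusive fragment
length that capillary sizing reports.

Coordinates are 0-based, half-open; lengths are integer base pairs and
include the labeled primer (the dye sits on the primer 5' end).
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "FORWARD",
    "REVERSE",
    "ENDS",
    "NO_CUT",
    "BELOW_WINDOW",
    "PrimerPair",
    "Enzyme",
    "MSPI",
    "HHAI",
    "HAEIII",
    "DEFAULT_ENZYMES",
    "DigestSignature",
    "PhylotypeRecord",
    "Amplicon",
    "PrimerNotFoundError",
    "reverse_complement",
    "locate_amplicon",
    "terminal_fragment",
    "signature",
    "read_fasta",
    "write_fasta",
    "write_signature_table",
]

FORWARD = "forward"
REVERSE = "reverse"
ENDS = (FORWARD, REVERSE)

#: 8F, carries HEX on its 5' end in the assay this emulates.
PRIMER_8F = "AGAGTTTGATCCTGGCTCAG"
#: 1492R, carries FAM; written 5'->3' on the reverse strand.
PRIMER_1492R = "GGTTACCTTGTTACGACTT"

IUPAC = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


class _Sentinel:
    """Singleton slot marker; compares by identity, survives repr round-trips."""

    __slots__ = ("_name",)

    def __init__(self, name: str):
        self._name = name

    def __repr__(self) -> str:
        return self._name

    def __deepcopy__(self, memo):
        return self

    def __copy__(self):
        return self


#: Recognition sequence absent from the amplicon (Table-style token "NC").
NO_CUT = _Sentinel("NO_CUT")
#: Fragment shorter than the reliable sizing window (Table-style token "<50").
BELOW_WINDOW = _Sentinel("BELOW_WINDOW")


class PrimerNotFoundError(ValueError):
    """The sequence is not amplifiable: a primer has no acceptable match."""

    def __init__(self, which: str, max_mismatches: int):
        self.which = which
        super().__init__(
            f"{which} primer not found at <= {max_mismatches} mismatches"
        )


@dataclass(frozen=True)
class PrimerPair:
    forward: str = PRIMER_8F
    reverse: str = PRIMER_1492R
    max_mismatches: int = 0

    def __post_init__(self):
        for name, seq in (("forward", self.forward), ("reverse", self.reverse)):
            if not seq:
                raise ValueError(f"{name} primer is empty")
            bad = set(seq.upper()) - set(IUPAC)
            if bad:
                raise ValueError(f"{name} primer has non-IUPAC symbols: {bad}")


@dataclass(frozen=True)
class Enzyme:
    """Restriction enzyme: recognition sequence plus the cut position
    (bases from recognition start) on the labeled strand."""

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self):
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError("cut_offset outside recognition sequence")

    @property
    def is_palindromic(self) -> bool:
        return reverse_complement(self.recognition) == self.recognition


MSPI = Enzyme("MspI", "CCGG", 1)     # C^CGG
HHAI = Enzyme("HhaI", "GCGC", 3)     # GCG^C
HAEIII = Enzyme("HaeIII", "GGCC", 2)  # GG^CC

#: Signature column order follows the clone-table convention:
#: forward MspI, HhaI, HaeIII then reverse MspI, HhaI, HaeIII.
DEFAULT_ENZYMES = (MSPI, HHAI, HAEIII)


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


class DigestSignature(Mapping):
    """Six-slot mapping (enzyme name, end) -> fragment length in bp,
    NO_CUT, or BELOW_WINDOW."""

    __slots__ = ("_slots",)

    def __init__(self, slots):
        self._slots = dict(slots)

    def __getitem__(self, key):
        return self._slots[key]

    def __iter__(self):
        return iter(self._slots)

    def __len__(self):
        return len(self._slots)

    def __eq__(self, other):
        if isinstance(other, DigestSignature):
            return self._slots == other._slots
        if isinstance(other, Mapping):
            return self._slots == dict(other)
        return NotImplemented

    def __hash__(self):
        return hash(frozenset(self._slots.items()))

    def __repr__(self):
        inner = ", ".join(f"{e}/{lab[0]}={v}" for (e, lab), v in self._slots.items())
        return f"DigestSignature({inner})"

    def as_row(self, enzymes=DEFAULT_ENZYMES):
        """Values in table column order (forward triplet, then reverse)."""
        return [self[(e.name, end)] for end in ENDS for e in enzymes]

    @classmethod
    def from_row(cls, values, enzymes=DEFAULT_ENZYMES):
        keys = [(e.name, end) for end in ENDS for e in enzymes]
        if len(values) != len(keys):
            raise ValueError(f"expected {len(keys)} slot values")
        return cls(zip(keys, values))


@dataclass
class PhylotypeRecord:
    """A named 16S-like sequence; `taxon` is the organism-level label and
    `group` the collapsed higher-taxon bin used in community matrices."""

    id: str
    sequence: str
    taxon: str = ""
    group: str = ""


@dataclass(frozen=True)
class Amplicon:
    """Amplified subsequence in forward orientation with its coordinates
    (0-based, half-open) on the source sequence."""

    sequence: str
    start: int
    end: int

    def __len__(self) -> int:
        return len(self.sequence)


def _iupac_hamming(window: str, primer: str) -> int:
    """Mismatch count; a position matches when the IUPAC sets intersect."""
    n = 0
    for w, p in zip(window, primer):
        if not (IUPAC.get(w.upper(), frozenset()) & IUPAC.get(p.upper(), frozenset())):
            n += 1
    return n


def _primer_matches(sequence: str, primer: str, max_mm: int) -> list[int]:
    m = len(primer)
    return [
        i
        for i in range(len(sequence) - m + 1)
        if _iupac_hamming(sequence[i : i + m], primer) <= max_mm
    ]


def locate_amplicon(sequence: str, primers: PrimerPair = PrimerPair()) -> Amplicon:
    """Find the amplicon spanned by the primer pair.

    The forward primer is matched directly on the given strand (first
    acceptable match); the reverse primer is matched as its reverse
    complement (last acceptable match downstream of the forward primer),
    so the returned amplicon runs from forward-primer start through the
    reverse-primer binding-site end, inclusive of both primers.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    mm = primers.max_mismatches
    fwd_hits = _primer_matches(seq, primers.forward, mm)
    if not fwd_hits:
        raise PrimerNotFoundError("forward", mm)
    start = fwd_hits[0]
    rc_rev = reverse_complement(primers.reverse)
    rev_hits = [
        i for i in _primer_matches(seq, rc_rev, mm) if i >= start + len(primers.forward)
    ]
    if not rev_hits:
        raise PrimerNotFoundError("reverse", mm)
    end = rev_hits[-1] + len(rc_rev)
    return Amplicon(seq[start:end], start, end)


def terminal_fragment(amplicon: str, enzyme: Enzyme, label: str = FORWARD):
    """Length of the labeled terminal fragment, or NO_CUT.

    For the forward label the fragment runs from amplicon position 0 to
    the cut inside the first recognition-site occurrence; for the reverse
    label the same scan is done on the reverse complement.
    """
    if not amplicon:
        raise ValueError("empty amplicon")
    if label not in ENDS:
        raise ValueError(f"label must be one of {ENDS}")
    seq = amplicon.upper() if label == FORWARD else reverse_complement(amplicon.upper())
    i = seq.find(enzyme.recognition.upper())
    if i < 0:
        return NO_CUT
    return i + enzyme.cut_offset


def signature(
    record: PhylotypeRecord | str,
    primers: PrimerPair = PrimerPair(),
    enzymes=DEFAULT_ENZYMES,
) -> DigestSignature:
    """Six-slot digest signature of a phylotype (or raw sequence)."""
    seq = record.sequence if isinstance(record, PhylotypeRecord) else record
    amp = locate_amplicon(seq, primers).sequence
    return DigestSignature(
        {
            (enz.name, end): terminal_fragment(amp, enz, end)
            for end in ENDS
            for enz in enzymes
        }
    )


# ---------------------------------------------------------------------------
# IO

def read_fasta(path: str | Path) -> list[PhylotypeRecord]:
    """Read phylotypes; the first description word after the id is kept as
    the taxon label and a `group=` token, when present, as the group."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        taxon, group = "", ""
        for tok in rec.description.split()[1:]:
            if tok.startswith("group="):
                group = tok[len("group="):]
            elif not taxon:
                taxon = tok
        records.append(PhylotypeRecord(rec.id, str(rec.seq).upper(), taxon, group))
    return records


def write_fasta(records, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            desc = ""
            if rec.taxon:
                desc += f" {rec.taxon}"
            if rec.group:
                desc += f" group={rec.group}"
            fh.write(f">{rec.id}{desc}\n")
            seq = rec.sequence
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def _slot_token(value) -> str:
    if value is NO_CUT:
        return "NC"
    if value is BELOW_WINDOW:
        return "<50"
    return str(value)


def write_signature_table(
    records,
    path: str | Path,
    primers: PrimerPair = PrimerPair(),
    enzymes=DEFAULT_ENZYMES,
) -> None:
    """TSV of six-slot signatures, columns in table order
    (forward then reverse triplet)."""
    cols = [f"{end}_{e.name}" for end in ENDS for e in enzymes]
    with open(path, "w") as fh:
        fh.write("phylotype_id\ttaxon\tgroup\t" + "\t".join(cols) + "\n")
        for rec in records:
            sig = signature(rec, primers, enzymes)
            row = "\t".join(_slot_token(v) for v in sig.as_row(enzymes))
            fh.write(f"{rec.id}\t{rec.taxon}\t{rec.group}\t{row}\n")
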