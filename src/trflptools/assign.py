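"""Six-of-six T-RF assignment and community-matrix construction.

A binned T-RF is assigned to a phylotype only when all six slots of the
in silico digest signature agree with the sample's electropherograms:
numeric slots within a size tolerance, no-cut / below-window slots
categorically.  Assigned phylotypes are collapsed into higher taxon
bins (e.g. one Desulfovibrio bin from several Desulfovibrio clones),
and every unassigned bin's area accumulates into an explicit unknown
fraction, so assigned + unknown = 1 per sample.

The primary fingerprint axis is the MspI forward (HEX) digest; the
other five digests corroborate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .digest import (
    BELOW_WINDOW,
    DEFAULT_ENZYMES,
    ENDS,
    FORWARD,
    NO_CUT,
    DigestSignature,
    PhylotypeRecord,
    PrimerPair,
    signature as digest_signature,
)
from .peaks import BinTable

__all__ = [
    "UNASSIGNED",
    "LibraryEntry",
    "SignatureLibrary",
    "CommunityMatrix",
    "match_signature",
    "collapse_groups",
    "build_matrix",
]

logger = logging.getLogger(__name__)

#: Returned when no library entry satisfies the six-of-six rule.
UNASSIGNED = None


def _is_numeric(slot) -> bool:
    return slot is not NO_CUT and slot is not BELOW_WINDOW


@dataclass(frozen=True)
class LibraryEntry:
    phylotype_id: str
    taxon: str
    group: str
    signature: DigestSignature


class SignatureLibrary:
    """Phylotype signatures with taxon and group labels."""

    def __init__(self, entries):
        self.entries = list(entries)
        ids = [e.phylotype_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("phylotype ids must be unique")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)

    def __getitem__(self, phylotype_id: str) -> LibraryEntry:
        for e in self.entries:
            if e.phylotype_id == phylotype_id:
                return e
        raise KeyError(phylotype_id)

    @classmethod
    def from_records(
        cls,
        records,
        primers: PrimerPair = PrimerPair(),
        enzymes=DEFAULT_ENZYMES,
    ) -> "SignatureLibrary":
        """In silico digestion of a phylotype clone library."""
        return cls(
            LibraryEntry(
                rec.id,
                rec.taxon or rec.id,
                rec.group or rec.taxon or rec.id,
                digest_signature(rec, primers, enzymes),
            )
            for rec in records
        )

    @classmethod
    def from_tsv(cls, path: str | Path, enzymes=DEFAULT_ENZYMES) -> "SignatureLibrary":
        """Read a library table; slot tokens 'NC' and '<50' are accepted."""
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        cols = [f"{end}_{e.name}" for end in ENDS for e in enzymes]
        entries = []
        for row in df.itertuples(index=False):
            values = []
            for col in cols:
                tok = str(getattr(row, col)).strip()
                if tok.upper() == "NC":
                    values.append(NO_CUT)
                elif tok.startswith("<"):
                    values.append(BELOW_WINDOW)
                else:
                    values.append(float(tok))
            entries.append(
                LibraryEntry(
                    str(row.phylotype_id),
                    str(getattr(row, "taxon", "") or ""),
                    str(getattr(row, "group", "") or "") or str(getattr(row, "taxon", "")),
                    DigestSignature.from_row(values, enzymes),
                )
            )
        return cls(entries)


@dataclass
class CommunityMatrix:
    """Samples x taxon-group bins of relative areas plus the per-sample
    unknown fraction; assigned + unknown = 1."""

    abundance: pd.DataFrame
    unknown: pd.Series

    def __post_init__(self):
        if not self.abundance.index.equals(self.unknown.index):
            raise ValueError("abundance and unknown must share the sample index")
        if (self.abundance.to_numpy() < -1e-12).any():
            raise ValueError("abundances must be non-negative")
        total = self.abundance.sum(axis=1) + self.unknown
        nonempty = (self.abundance.sum(axis=1) + self.unknown) > 0
        if not np.allclose(total[nonempty], 1.0, atol=1e-9):
            raise ValueError("assigned + unknown must equal 1 per sample")

    @property
    def samples(self) -> list:
        return list(self.abundance.index)


def _slot_deviation(observed_slot, library_slot, tol: float):
    """None if the slots disagree, else the absolute deviation."""
    obs_num, lib_num = _is_numeric(observed_slot), _is_numeric(library_slot)
    if obs_num != lib_num:
        return None
    if not obs_num:
        return 0.0  # NO_CUT / below-window agree categorically
    dev = abs(float(observed_slot) - float(library_slot))
    return dev if dev <= tol else None


def match_signature(
    observed: DigestSignature,
    library: SignatureLibrary,
    tol: float = 1.0,
):
    """Six-of-six matching of one observed signature.

    An entry matches iff every slot agrees (numeric within `tol` bp,
    categorical otherwise).  A unique match wins; several matches go to
    the nearest by summed absolute slot deviation; an exact tie is
    UNASSIGNED with a logged ambiguity.
    """
    if tol < 0:
        raise ValueError("tol must be non-negative")
    scored = []
    for entry in library:
        total = 0.0
        for key, lib_slot in entry.signature.items():
            dev = _slot_deviation(observed.get(key, BELOW_WINDOW), lib_slot, tol)
            if dev is None:
                total = None
                break
            total += dev
        if total is not None:
            scored.append((total, entry))
    if not scored:
        return UNASSIGNED
    scored.sort(key=lambda t: t[0])
    if len(scored) > 1 and abs(scored[0][0] - scored[1][0]) < 1e-12:
        logger.warning(
            "ambiguous six-of-six match: %s vs %s at equal deviation %.3f",
            scored[0][1].phylotype_id, scored[1][1].phylotype_id, scored[0][0],
        )
        return UNASSIGNED
    return scored[0][1].phylotype_id


def collapse_groups(assignments: dict, library: SignatureLibrary) -> dict:
    """Sum areas of phylotypes sharing a group label.

    `assignments` maps phylotype_id -> area; returns group -> area.
    Total area is conserved.
    """
    collapsed: dict = {}
    for pid, area in assignments.items():
        group = library[pid].group
        collapsed[group] = collapsed.get(group, 0.0) + area
    return collapsed


def build_matrix(
    bin_tables: dict,
    library: SignatureLibrary,
    tol: float = 1.0,
    primary=("MspI", FORWARD),
) -> CommunityMatrix:
    """Assign binned T-RFs and assemble the community matrix.

    `bin_tables` maps (enzyme name, end) -> BinTable; `primary` names
    the fingerprint axis whose relative areas are quantified.  For each
    sample and primary bin, a library entry matches when its primary
    slot matches the bin center within `tol` and each remaining slot is
    corroborated by that sample's corresponding digest: numeric slots by
    some bin within `tol`, NC/below-window slots categorically (a digest
    with no nearby peak is treated as below-window).  Unmatched bin
    areas accumulate into the per-sample unknown fraction.
    """
    if tol < 0:
        raise ValueError("tol must be non-negative")
    if primary not in bin_tables:
        raise KeyError(f"primary digest {primary} missing from bin_tables")
    primary_table = bin_tables[primary]
    samples = primary_table.samples
    slot_keys = list(next(iter(library)).signature) if len(library) else []

    # per sample and digest: bin centers with nonzero area
    sample_centers: dict = {}
    for key, bt in bin_tables.items():
        arr = bt.table
        for sid in samples:
            if sid in arr.columns:
                present = arr.index.to_numpy(dtype=float)[arr[sid].to_numpy() > 0]
            else:
                present = np.empty(0)
            sample_centers[(key, sid)] = present

    groups = sorted({e.group for e in library})
    abundance = pd.DataFrame(0.0, index=pd.Index(samples, name="sample_id"), columns=groups)
    unknown = pd.Series(0.0, index=abundance.index, name="unknown")

    centers = primary_table.centers
    for sid in samples:
        areas = primary_table.table[sid].to_numpy()
        for center, area in zip(centers, areas):
            if area <= 0:
                continue
            scored = []
            for entry in library:
                lib_primary = entry.signature[primary]
                if not _is_numeric(lib_primary) or abs(center - float(lib_primary)) > tol:
                    continue
                total = abs(center - float(lib_primary))
                ok = True
                for key in slot_keys:
                    if key == primary:
                        continue
                    lib_slot = entry.signature[key]
                    present = sample_centers.get((key, sid), np.empty(0))
                    if _is_numeric(lib_slot):
                        if present.size == 0:
                            ok = False
                            break
                        dev = np.abs(present - float(lib_slot)).min()
                        if dev > tol:
                            ok = False
                            break
                        total += dev
                    # NC / below-window: categorically satisfied
                if ok:
                    scored.append((total, entry))
            if not scored:
                unknown[sid] += area
                continue
            scored.sort(key=lambda t: t[0])
            if len(scored) > 1 and abs(scored[0][0] - scored[1][0]) < 1e-12:
                logger.warning(
                    "sample %s bin %.1f: ambiguous assignment (%s vs %s)",
                    sid, center, scored[0][1].phylotype_id, scored[1][1].phylotype_id,
                )
                unknown[sid] += area
                continue
            abundance.loc[sid, scored[0][1].group] += area
    return CommunityMatrix(abundance=abundance, unknown=unknown)
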