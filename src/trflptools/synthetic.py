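"""Synthetic study generator: planted digest signatures, noisy duplicate
electropherograms, and a mineral x carbon x dilution Fe-reduction grid.

Everything downstream (digestion, peak cleaning, assignment, clustering,
selection) can be exercised against known ground truth because the
generator plants it: sequences are built backwards from a requested
six-slot digest signature, peak profiles are built from a known
community, and the Fe grid is built from explicit dilution-response
shapes.  All randomness flows from explicit seeds.

Sequence backgrounds are uniform over {A,C,G,T} with rejection of
accidental recognition sites, which guarantees signature correctness
without making any biological-realism claim.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .digest import (
    DEFAULT_ENZYMES,
    ENDS,
    FORWARD,
    NO_CUT,
    REVERSE,
    DigestSignature,
    Enzyme,
    PhylotypeRecord,
    PrimerPair,
    locate_amplicon,
    reverse_complement,
    terminal_fragment,
    signature,
)
from .peaks import PeakProfile
from .thermo import EnrichmentRecord

__all__ = [
    "FORWARD_DYE",
    "REVERSE_DYE",
    "DYE_TO_END",
    "InfeasibleSignatureError",
    "EmptyCommunityError",
    "SyntheticCommunity",
    "NoiseSpec",
    "ShapeSpec",
    "FeGridSpec",
    "plant_signature",
    "random_feasible_signature",
    "generate_community",
    "synthesize_profiles",
    "default_fe_grid_spec",
    "generate_fe_grid",
    "carbon_structured_panel",
    "StudyData",
    "simulate_study",
]

#: Dye labels as emitted in peak tables; HEX rides the forward primer,
#: FAM the reverse, matching the dual-labeled primer setup.
FORWARD_DYE = "HEX"
REVERSE_DYE = "FAM"
DYE_TO_END = {FORWARD_DYE: FORWARD, REVERSE_DYE: REVERSE,
              FORWARD: FORWARD, REVERSE: REVERSE}

BASES = np.array(list("ACGT"))

MINERALS = ("ferrihydrite", "goethite", "hematite")
CARBONS = ("acetate", "lactate", "glucose", "mixed")
MINERAL_CODE = {"ferrihydrite": "F", "goethite": "G", "hematite": "H"}
CARBON_CODE = {"acetate": "A", "lactate": "L", "glucose": "G", "mixed": "M"}

#: Geobacter-like clone signature used to anchor the default panel
#: (forward MspI/HhaI/HaeIII then reverse, bp).
GEOBACTER_SIGNATURE = (164, 93, 217, 126, 405, 124)


class InfeasibleSignatureError(ValueError):
    """The requested signature cannot be realized; `slots` names the
    conflicting (enzyme, end) slots."""

    def __init__(self, message: str, slots=()):
        self.slots = tuple(slots)
        super().__init__(message)


class EmptyCommunityError(ValueError):
    pass


@dataclass
class SyntheticCommunity:
    """Known community: member phylotypes plus relative abundances."""

    members: tuple
    abundances: np.ndarray

    def __post_init__(self):
        self.members = tuple(self.members)
        self.abundances = np.asarray(self.abundances, dtype=float)
        if len(self.members) == 0:
            raise EmptyCommunityError("community has no members")
        if len(self.members) != len(self.abundances):
            raise ValueError("members and abundances differ in length")
        if np.any(self.abundances < 0):
            raise ValueError("abundances must be non-negative")
        if abs(self.abundances.sum() - 1.0) > 1e-9:
            raise ValueError("abundances must sum to 1")
        ids = [m.id for m in self.members]
        if len(set(ids)) != len(ids):
            raise ValueError("member ids must be unique")

    @property
    def taxa(self) -> list[str]:
        return [m.taxon or m.id for m in self.members]


@dataclass(frozen=True)
class NoiseSpec:
    """Electropherogram degradation model: spurious peaks with small
    areas, per-replicate size jitter, and rare per-replicate dropout of
    true peaks.  Defaults reflect a clean capillary run: many low-area
    noise peaks, ~0.1 bp sizing repeatability, and essentially no
    dropout of major peaks."""

    n_noise_peaks: int = 60
    noise_area_scale: float = 40.0
    size_jitter_sd: float = 0.1
    dropout_prob: float = 0.001

    def __post_init__(self):
        if self.n_noise_peaks < 0 or self.noise_area_scale < 0 or self.size_jitter_sd < 0:
            raise ValueError("noise parameters must be non-negative")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValueError("dropout_prob must be in [0, 1]")

    @classmethod
    def none(cls) -> "NoiseSpec":
        return cls(0, 0.0, 0.0, 0.0)


# ---------------------------------------------------------------------------
# Signature planting

def _normalize_target(target, enzymes) -> dict:
    slots = dict(target)
    full = {}
    for enz in enzymes:
        for end in ENDS:
            full[(enz.name, end)] = slots.get((enz.name, end), NO_CUT)
    return full


def _site_positions(target: dict, enzymes, amplicon_length: int,
                    primers: PrimerPair) -> dict:
    """Map enzyme name -> {start position: enzyme} of planted sites in
    forward coordinates; raises on inconsistent requests."""
    L = amplicon_length
    n_fwd, n_rev = len(primers.forward), len(primers.reverse)
    planted: dict[str, set[int]] = {}
    for enz in enzymes:
        tf = target[(enz.name, FORWARD)]
        tr = target[(enz.name, REVERSE)]
        f_num, r_num = tf is not NO_CUT, tr is not NO_CUT
        if enz.is_palindromic and f_num != r_num:
            raise InfeasibleSignatureError(
                f"{enz.name}: a palindromic recognition site cut on one strand is "
                "also present on the other, so its forward and reverse slots must "
                "be jointly numeric or jointly NO_CUT",
                slots=[(enz.name, FORWARD), (enz.name, REVERSE)],
            )
        sites: set[int] = set()
        m = len(enz.recognition)
        if f_num:
            if tf < n_fwd or tf > L:
                raise InfeasibleSignatureError(
                    f"{enz.name} forward fragment {tf} outside [primer length, amplicon length]",
                    slots=[(enz.name, FORWARD)],
                )
            f0 = tf - enz.cut_offset
            if f0 < 0 or f0 + m > L:
                raise InfeasibleSignatureError(
                    f"{enz.name} forward site does not fit in the amplicon",
                    slots=[(enz.name, FORWARD)],
                )
            sites.add(f0)
        if r_num:
            if tr < n_rev or tr > L:
                raise InfeasibleSignatureError(
                    f"{enz.name} reverse fragment {tr} outside [primer length, amplicon length]",
                    slots=[(enz.name, REVERSE)],
                )
            r0 = L - (tr - enz.cut_offset) - m
            if r0 < 0 or r0 + m > L:
                raise InfeasibleSignatureError(
                    f"{enz.name} reverse site does not fit in the amplicon",
                    slots=[(enz.name, REVERSE)],
                )
            if f_num:
                f0 = tf - enz.cut_offset
                if r0 < f0:
                    raise InfeasibleSignatureError(
                        f"{enz.name}: requested forward site (first occurrence) lies "
                        "after the requested reverse site (last occurrence)",
                        slots=[(enz.name, FORWARD), (enz.name, REVERSE)],
                    )
            sites.add(r0)
        planted[enz.name] = sites
    return planted


def _forbidden_occurrence(seq: list, enzymes, planted: dict):
    """First occurrence of any recognition sequence outside its planted
    positions, or None."""
    text = "".join(seq)
    for enz in enzymes:
        rec = enz.recognition
        start = 0
        while True:
            i = text.find(rec, start)
            if i < 0:
                break
            if i not in planted[enz.name]:
                return i, enz
            start = i + 1
    return None


def plant_signature(
    target,
    amplicon_length: int = 1450,
    seed: int | None = None,
    primers: PrimerPair = PrimerPair(),
    enzymes=DEFAULT_ENZYMES,
    record_id: str = "planted",
    taxon: str = "",
    group: str = "",
    max_tries: int = 30,
) -> PhylotypeRecord:
    """Construct a sequence whose digest signature equals `target`.

    The sequence begins with the forward primer and ends with the
    reverse complement of the reverse primer; recognition sites are
    stamped at the positions the requested fragment lengths imply and
    every accidental occurrence elsewhere is rejected.  Slots omitted
    from `target` are treated as NO_CUT.  Infeasible requests (e.g. a
    palindromic enzyme cut on only one strand, or overlapping sites
    demanding different bases) raise InfeasibleSignatureError naming the
    conflicting slots.
    """
    target_full = _normalize_target(target, enzymes)
    L = amplicon_length
    fwd = primers.forward.upper()
    rc_rev = reverse_complement(primers.reverse.upper())
    if L < len(fwd) + len(rc_rev):
        raise ValueError("amplicon shorter than the two primers")
    if set(fwd + rc_rev) - set("ACGT"):
        raise ValueError("planting requires concrete (non-ambiguous) primers")
    planted = _site_positions(target_full, enzymes, L, primers)

    # fixed template: primers, then planted sites (compatible overlaps merge)
    template: list = [None] * L
    for i, ch in enumerate(fwd):
        template[i] = ch
    for i, ch in enumerate(rc_rev):
        template[L - len(rc_rev) + i] = ch
    for enz in enzymes:
        rec = enz.recognition
        for pos in planted[enz.name]:
            for off, ch in enumerate(rec):
                cur = template[pos + off]
                if cur is not None and cur != ch:
                    raise InfeasibleSignatureError(
                        f"planted {enz.name} site at {pos} conflicts with a fixed "
                        f"base at position {pos + off}",
                        slots=[(enz.name, end) for end in ENDS
                               if target_full[(enz.name, end)] is not NO_CUT],
                    )
                template[pos + off] = ch
    fixed = [ch is not None for ch in template]

    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        seq = list(template)
        free_idx = [i for i in range(L) if not fixed[i]]
        fill = rng.choice(BASES, size=len(free_idx))
        for i, ch in zip(free_idx, fill):
            seq[i] = str(ch)
        ok = True
        for _ in range(50 * L):
            hit = _forbidden_occurrence(seq, enzymes, planted)
            if hit is None:
                break
            pos, enz = hit
            free_in_site = [
                p for p in range(pos, pos + len(enz.recognition)) if not fixed[p]
            ]
            if not free_in_site:
                raise InfeasibleSignatureError(
                    f"an unavoidable {enz.name} site at position {pos} is fully "
                    "determined by primers/planted sites",
                    slots=[(enz.name, end) for end in ENDS],
                )
            p = int(rng.choice(free_in_site))
            bad = enz.recognition[p - pos]
            seq[p] = str(rng.choice(BASES[BASES != bad]))
        else:
            ok = False
        if not ok:
            continue
        sequence = "".join(seq)
        realized = signature(sequence, PrimerPair(primers.forward, primers.reverse, 0),
                             enzymes)
        if realized == DigestSignature(target_full):
            return PhylotypeRecord(record_id, sequence, taxon, group)
    raise InfeasibleSignatureError(
        f"could not realize the requested signature in {max_tries} attempts"
    )


def random_feasible_signature(
    rng: np.random.Generator,
    amplicon_length: int = 1450,
    primers: PrimerPair = PrimerPair(),
    enzymes=DEFAULT_ENZYMES,
    p_nocut: float = 0.2,
    window: tuple = (55, 545),
    min_separation: int = 8,
    max_tries: int = 200,
) -> DigestSignature:
    """Draw a signature guaranteed plantable: per enzyme either both
    slots NO_CUT or both numeric, with site intervals inside the sizing
    window and pairwise separated by at least `min_separation` bp."""
    L = amplicon_length
    n_fwd, n_rev = len(primers.forward), len(primers.reverse)
    lo, hi = window
    for _ in range(max_tries):
        slots, intervals = {}, []
        ok = True
        for enz in enzymes:
            m = len(enz.recognition)
            if rng.random() < p_nocut:
                slots[(enz.name, FORWARD)] = NO_CUT
                slots[(enz.name, REVERSE)] = NO_CUT
                continue
            f_lo = max(n_fwd, lo - enz.cut_offset)
            f_hi = min(L - n_rev - m, hi - enz.cut_offset)
            r_lo = max(n_fwd, L - hi - m + enz.cut_offset)
            r_hi = min(L - n_rev - m, L - lo - m + enz.cut_offset)
            if f_lo > f_hi or r_lo > r_hi:
                ok = False
                break
            f0 = int(rng.integers(f_lo, f_hi + 1))
            r_lo = max(r_lo, f0 + m + min_separation)
            if r_lo > r_hi:
                ok = False
                break
            r0 = int(rng.integers(r_lo, r_hi + 1))
            intervals.extend([(f0, f0 + m), (r0, r0 + m)])
            slots[(enz.name, FORWARD)] = f0 + enz.cut_offset
            slots[(enz.name, REVERSE)] = L - r0 - m + enz.cut_offset
        if not ok:
            continue
        intervals.sort()
        if all(b[0] - a[1] >= min_separation for a, b in zip(intervals, intervals[1:])):
            return DigestSignature(slots)
    raise InfeasibleSignatureError(
        "could not draw a feasible signature for this amplicon length/window"
    )


# ---------------------------------------------------------------------------
# Communities and profiles

def generate_community(
    n_taxa: int | None = None,
    concentration: float = 1.0,
    seed: int | None = None,
    members=None,
) -> SyntheticCommunity:
    """Symmetric-Dirichlet community over `members` (or anonymous
    placeholder phylotypes when only `n_taxa` is given)."""
    if members is not None:
        members = tuple(members)
        n_taxa = len(members)
    if not n_taxa:
        raise EmptyCommunityError("n_taxa must be >= 1")
    if concentration <= 0:
        raise ValueError("Dirichlet concentration must be positive")
    if members is None:
        members = tuple(
            PhylotypeRecord(f"taxon{i}", "", taxon=f"taxon{i}") for i in range(n_taxa)
        )
    rng = np.random.default_rng(seed)
    abundances = rng.dirichlet([concentration] * n_taxa)
    return SyntheticCommunity(members, abundances)


def synthesize_profiles(
    community: SyntheticCommunity | None,
    enzyme: Enzyme,
    dye_end: str,
    noise: NoiseSpec = NoiseSpec(),
    n_replicates: int = 2,
    seed: int | None = None,
    sample_id: str = "S1",
    primers: PrimerPair = PrimerPair(),
    total_area: float = 1e4,
) -> list[PeakProfile]:
    """Replicate electropherograms for a known community.

    True peaks sit at the members' T-RF sizes (non-cutting members
    contribute an uncut full-amplicon-length peak) with areas
    proportional to abundance; each replicate gets independent size
    jitter, dropout, and noise peaks per `noise`.
    """
    end = DYE_TO_END[dye_end]
    dye = FORWARD_DYE if end == FORWARD else REVERSE_DYE
    if community is None or len(getattr(community, "members", ())) == 0:
        return [PeakProfile(sample_id, enzyme.name, dye, r) for r in range(n_replicates)]
    rng = np.random.default_rng(seed)
    true_sizes, true_areas = [], []
    for member, abundance in zip(community.members, community.abundances):
        amp = locate_amplicon(member.sequence, primers)
        trf = terminal_fragment(amp.sequence, enzyme, end)
        true_sizes.append(float(len(amp) if trf is NO_CUT else trf))
        true_areas.append(abundance * total_area)
    true_sizes = np.array(true_sizes)
    true_areas = np.array(true_areas)
    profiles = []
    for rep in range(n_replicates):
        jitter = rng.normal(0.0, noise.size_jitter_sd, size=len(true_sizes))
        keep = rng.random(len(true_sizes)) >= noise.dropout_prob
        sizes = (true_sizes + jitter)[keep]
        areas = true_areas[keep]
        if noise.n_noise_peaks:
            nsizes = rng.uniform(30.0, 600.0, size=noise.n_noise_peaks)
            nareas = rng.exponential(noise.noise_area_scale, size=noise.n_noise_peaks)
            sizes = np.concatenate([sizes, nsizes])
            areas = np.concatenate([areas, nareas])
        profiles.append(PeakProfile(sample_id, enzyme.name, dye, rep, sizes, areas))
    return profiles


# ---------------------------------------------------------------------------
# Fe-reduction grid

SHAPE_TAGS = ("decreasing", "unimodal_at_third", "flat_low")
DECREASING_TEMPLATE = (1.00, 0.85, 0.55, 0.25, 0.10)
UNIMODAL_TEMPLATE = (0.15, 0.50, 1.00, 0.50, 0.08)


@dataclass(frozen=True)
class ShapeSpec:
    tag: str
    amp_range: tuple

    def __post_init__(self):
        if self.tag not in SHAPE_TAGS:
            raise ValueError(f"shape tag must be one of {SHAPE_TAGS}")
        lo, hi = self.amp_range
        if not (0 <= lo <= hi <= 100):
            raise ValueError("amplitude range must lie in [0, 100]")


@dataclass
class FeGridSpec:
    """Dilution-response shape per (mineral, carbon); additive Gaussian
    noise (sd in percentage points, truncated to [0, 100]) models
    between-enrichment scatter."""

    shapes: dict
    noise_sd: float = 2.0
    fetot_mM: float = 25.0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def default_fe_grid_spec(noise_sd: float = 2.0) -> FeGridSpec:
    """Default grid mirroring the observed mineral x carbon pattern:
    ferrihydrite reduced at low dilutions under every carbon source
    (84-88% under acetate), crystalline oxides reduced substantially
    (56-67%, peaking at the third dilution) only under fermentable
    carbon — all three such goethite sources but only glucose on
    hematite — and essentially no reduction of crystalline oxides under
    acetate."""
    shapes = {}
    for carbon in CARBONS:
        shapes[("ferrihydrite", carbon)] = ShapeSpec(
            "decreasing", (84, 88) if carbon == "acetate" else (70, 90)
        )
    for carbon in ("lactate", "glucose", "mixed"):
        shapes[("goethite", carbon)] = ShapeSpec("unimodal_at_third", (56, 67))
    shapes[("goethite", "acetate")] = ShapeSpec("flat_low", (0, 4))
    shapes[("hematite", "glucose")] = ShapeSpec("unimodal_at_third", (56, 67))
    for carbon in ("acetate", "lactate", "mixed"):
        shapes[("hematite", carbon)] = ShapeSpec("flat_low", (0, 4))
    return FeGridSpec(shapes=shapes, noise_sd=noise_sd)


def generate_fe_grid(
    spec: FeGridSpec | None = None,
    seed: int | None = None,
    n_replicates: int = 2,
    dilutions=(1, 2, 3, 4, 5),
) -> list[EnrichmentRecord]:
    """Generate the enrichment grid (default 3 minerals x 4 carbons x 5
    dilutions x 2 duplicates = 120 records, FeTOT fixed at 25 mM)."""
    spec = spec or default_fe_grid_spec()
    missing = [
        (m, c) for m in MINERALS for c in CARBONS if (m, c) not in spec.shapes
    ]
    if missing:
        raise ValueError(f"FeGridSpec missing mineral x carbon combinations: {missing}")
    rng = np.random.default_rng(seed)
    records = []
    for mineral in MINERALS:
        for carbon in CARBONS:
            shape = spec.shapes[(mineral, carbon)]
            lo, hi = shape.amp_range
            for rep in range(n_replicates):
                amp = rng.uniform(lo, hi)
                for i, dil in enumerate(dilutions):
                    if shape.tag == "decreasing":
                        target = amp * DECREASING_TEMPLATE[i % len(DECREASING_TEMPLATE)]
                    elif shape.tag == "unimodal_at_third":
                        target = amp * UNIMODAL_TEMPLATE[i % len(UNIMODAL_TEMPLATE)]
                    else:  # flat_low
                        target = amp * rng.uniform(0.3, 1.0)
                    observed = float(
                        np.clip(target + rng.normal(0.0, spec.noise_sd), 0.0, 100.0)
                    )
                    sid = (
                        f"{MINERAL_CODE[mineral]}{CARBON_CODE[carbon]}"
                        f"{dil}{chr(ord('A') + rep)}"
                    )
                    records.append(
                        EnrichmentRecord(
                            sample_id=sid,
                            mineral=mineral,
                            carbon=carbon,
                            dilution_exponent=dil,
                            fe2_mM=observed / 100.0 * spec.fetot_mM,
                            fetot_mM=spec.fetot_mM,
                            target_percent=float(target),
                        )
                    )
    return records


# ---------------------------------------------------------------------------
# Whole-study simulation

def carbon_structured_panel(
    seed: int | None = None,
    carbons=("acetate", "lactate", "glucose"),
    taxa_per_pool: int = 5,
    amplicon_length: int = 1450,
    primers: PrimerPair = PrimerPair(),
    enzymes=DEFAULT_ENZYMES,
    min_primary_separation: float = 3.0,
):
    """Phylotype panel with one disjoint taxon pool per carbon source.

    All signatures are fully numeric inside the sizing window and their
    primary (MspI forward) fragments are pairwise separated so bins map
    uniquely onto phylotypes.  The acetate pool is anchored by a
    Geobacter-like clone planted with the reference six-slot signature;
    the first two lactate-pool members share a Desulfovibrio-style group
    label to exercise taxon-bin collapsing.
    """
    rng = np.random.default_rng(seed)
    pools: dict[str, list[PhylotypeRecord]] = {}
    used_primary: list[float] = []
    primary_key = (enzymes[0].name, FORWARD)
    for carbon in carbons:
        pool = []
        for i in range(taxa_per_pool):
            if carbon == "acetate" and i == 0:
                sig = DigestSignature.from_row(GEOBACTER_SIGNATURE, enzymes)
                taxon = group = "Geobacter"
            else:
                while True:
                    sig = random_feasible_signature(
                        rng, amplicon_length, primers, enzymes, p_nocut=0.0
                    )
                    primary = sig[primary_key]
                    if all(
                        abs(primary - u) >= min_primary_separation
                        for u in used_primary
                    ):
                        break
                taxon = f"{carbon.capitalize()}Taxon{i}"
                group = taxon
                if carbon == "lactate" and i < 2:
                    group = "Desulfovibrio"
            used_primary.append(float(sig[primary_key]))
            rec = plant_signature(
                sig,
                amplicon_length,
                seed=int(rng.integers(0, 2**31)),
                primers=primers,
                enzymes=enzymes,
                record_id=f"{carbon[:3].upper()}-{i}",
                taxon=taxon,
                group=group,
            )
            pool.append(rec)
        pools[carbon] = pool
    return pools


@dataclass
class StudyData:
    """Ground-truth bundle produced by simulate_study."""

    pools: dict
    communities: dict
    profiles: list
    fe_records: list
    metadata: "object"  # pandas DataFrame: sample_id, mineral, carbon, dilution

    @property
    def records(self) -> list[PhylotypeRecord]:
        return [rec for pool in self.pools.values() for rec in pool]


def simulate_study(
    seed: int | None = None,
    carbons=("acetate", "lactate", "glucose"),
    minerals=MINERALS,
    n_dilutions: int = 5,
    taxa_per_pool: int = 5,
    concentration: float = 5.0,
    noise: NoiseSpec = NoiseSpec(),
    n_replicates: int = 2,
    amplicon_length: int = 1450,
    primers: PrimerPair = PrimerPair(),
    enzymes=DEFAULT_ENZYMES,
    fe_spec: FeGridSpec | None = None,
) -> StudyData:
    """Generate a full synthetic study.

    T-RFLP samples cover carbons x minerals x dilutions; each sample's
    community is drawn from its carbon source's taxon pool (carbon
    source structures the communities; mineral and dilution only label
    them).  Six electropherograms (3 enzymes x 2 dyes) are produced per
    sample in duplicate, plus the full 120-enrichment Fe grid.
    """
    import pandas as pd

    master = np.random.default_rng(seed)
    pools = carbon_structured_panel(
        int(master.integers(0, 2**31)), carbons, taxa_per_pool,
        amplicon_length, primers, enzymes,
    )
    communities, profiles, meta_rows = {}, [], []
    for mineral in minerals:
        for carbon in carbons:
            for dil in range(1, n_dilutions + 1):
                sid = f"{MINERAL_CODE[mineral]}{CARBON_CODE[carbon]}{dil}"
                community = generate_community(
                    concentration=concentration,
                    seed=int(master.integers(0, 2**31)),
                    members=pools[carbon],
                )
                communities[sid] = community
                for enz in enzymes:
                    for dye in (FORWARD_DYE, REVERSE_DYE):
                        profiles.extend(
                            synthesize_profiles(
                                community, enz, dye, noise, n_replicates,
                                seed=int(master.integers(0, 2**31)),
                                sample_id=sid, primers=primers,
                            )
                        )
                meta_rows.append(
                    {"sample_id": sid, "mineral": mineral, "carbon": carbon,
                     "dilution_exponent": dil}
                )
    fe_records = generate_fe_grid(fe_spec, seed=int(master.integers(0, 2**31)))
    return StudyData(
        pools=pools,
        communities=communities,
        profiles=profiles,
        fe_records=fe_records,
        metadata=pd.DataFrame(meta_rows),
    )
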