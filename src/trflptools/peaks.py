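"""Electropherogram peak cleaning.

Raw T-RFLP data arrives as (fragment size, peak area) lists, one profile
per sample x enzyme x dye x replicate digest.  Cleaning proceeds:

1. export_window   — keep the 50–550 bp range where sizing is reliable;
2. denoise         — iterative signal/noise discrimination on relativized
                     peak areas (3-sigma-about-zero rule);
3. consensus_duplicates — keep only peaks present in both replicate
                     digests, at mean size and mean relative area;
4. bin_across_samples — single-linkage alignment of peak sizes into bins
                     shared across samples.

Relative areas are used throughout after consensus, which corrects for
differences in the amount of DNA injected per digest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PeakProfile",
    "BinTable",
    "export_window",
    "denoise",
    "consensus_duplicates",
    "bin_across_samples",
    "read_peak_table",
    "write_peak_table",
]


@dataclass
class PeakProfile:
    """One electropherogram reduced to peaks.

    `dye` identifies the labeled end ("HEX" = forward primer label,
    "FAM" = reverse), matching the dual-labeled primer setup.
    """

    sample_id: str
    enzyme: str
    dye: str
    replicate: int
    sizes: np.ndarray = field(default_factory=lambda: np.empty(0))
    areas: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        self.sizes = np.asarray(self.sizes, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if self.sizes.shape != self.areas.shape or self.sizes.ndim != 1:
            raise ValueError("sizes and areas must be 1-D arrays of equal length")
        if np.any(self.sizes <= 0):
            raise ValueError("peak sizes must be strictly positive")
        if np.any(self.areas < 0):
            raise ValueError("peak areas must be non-negative")
        order = np.argsort(self.sizes, kind="stable")
        self.sizes = self.sizes[order]
        self.areas = self.areas[order]

    @property
    def n_peaks(self) -> int:
        return len(self.sizes)

    def relative_areas(self) -> np.ndarray:
        total = self.areas.sum()
        return self.areas / total if total > 0 else self.areas.copy()

    def key(self) -> tuple:
        return (self.sample_id, self.enzyme, self.dye)


@dataclass
class BinTable:
    """Cross-sample T-RF bins: `table` is bins x samples of relative
    areas (index = bin centers in bp, strictly increasing)."""

    table: pd.DataFrame
    enzyme: str = ""
    dye: str = ""

    def __post_init__(self):
        centers = self.table.index.to_numpy(dtype=float)
        if len(centers) > 1 and not np.all(np.diff(centers) > 0):
            raise ValueError("bin centers must be strictly increasing")
        sums = self.table.to_numpy().sum(axis=0)
        ok = np.isclose(sums, 1.0, atol=1e-9) | np.isclose(sums, 0.0, atol=1e-9)
        if not ok.all():
            bad = list(self.table.columns[~ok])
            raise ValueError(f"per-sample relative areas must sum to 1 (or 0): {bad}")

    @property
    def centers(self) -> np.ndarray:
        return self.table.index.to_numpy(dtype=float)

    @property
    def samples(self) -> list:
        return list(self.table.columns)


def export_window(profile: PeakProfile, low: float = 50.0, high: float = 550.0) -> PeakProfile:
    """Keep peaks with low <= size <= high (inclusive bounds)."""
    if low > high:
        raise ValueError("window low bound exceeds high bound")
    keep = (profile.sizes >= low) & (profile.sizes <= high)
    return replace(profile, sizes=profile.sizes[keep], areas=profile.areas[keep])


def denoise(profile: PeakProfile, k: float = 3.0) -> PeakProfile:
    """Iterative signal/noise discrimination.

    Areas are relativized; the standard deviation of the not-yet-flagged
    areas about zero is computed, every peak exceeding k*sigma is flagged
    as signal, and the rule is repeated on the unflagged remainder until
    no new peak is flagged.  If the cascade never flags anything the whole
    profile is retained as all-signal rather than annihilated — low-
    diversity true profiles (few peaks, no noise floor) land here.
    Profiles with fewer than 3 peaks are returned unchanged (the noise
    sigma is meaningless).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    n = profile.n_peaks
    if n < 3:
        return replace(profile, sizes=profile.sizes.copy(), areas=profile.areas.copy())
    rel = profile.relative_areas()
    flagged = np.zeros(n, dtype=bool)
    while True:
        rest = rel[~flagged]
        if rest.size == 0:
            break
        sigma = float(np.sqrt(np.mean(rest**2)))
        new = (~flagged) & (rel > k * sigma)
        if not new.any():
            break
        flagged |= new
    if not flagged.any():
        return replace(profile, sizes=profile.sizes.copy(), areas=profile.areas.copy())
    return replace(profile, sizes=profile.sizes[flagged], areas=profile.areas[flagged])


def _greedy_pairs(a_sizes: np.ndarray, b_sizes: np.ndarray, tol: float):
    """Nearest-first greedy matching; each peak matches at most once."""
    cand = [
        (abs(sa - sb), i, j)
        for i, sa in enumerate(a_sizes)
        for j, sb in enumerate(b_sizes)
        if abs(sa - sb) <= tol
    ]
    cand.sort()
    used_a, used_b, pairs = set(), set(), []
    for _, i, j in cand:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j))
    return pairs


def consensus_duplicates(a: PeakProfile, b: PeakProfile, tol: float = 0.5) -> PeakProfile:
    """Duplicate-digest consensus.

    Each replicate is relativized first (injection-amount correction),
    peaks matched within `tol` bp are kept at mean size and mean relative
    area, unmatched peaks are discarded, and the result is re-relativized.
    """
    if a.key() != b.key():
        raise ValueError(f"profile keys differ: {a.key()} vs {b.key()}")
    if tol < 0:
        raise ValueError("tol must be non-negative")
    ra, rb = a.relative_areas(), b.relative_areas()
    pairs = _greedy_pairs(a.sizes, b.sizes, tol)
    if not pairs:
        return PeakProfile(a.sample_id, a.enzyme, a.dye, 0)
    sizes = np.array([(a.sizes[i] + b.sizes[j]) / 2 for i, j in pairs])
    areas = np.array([(ra[i] + rb[j]) / 2 for i, j in pairs])
    areas = areas / areas.sum()
    return PeakProfile(a.sample_id, a.enzyme, a.dye, 0, sizes, areas)


def bin_across_samples(profiles, gap: float = 1.0, enzyme: str = "", dye: str = "") -> BinTable:
    """Single-linkage alignment of peak sizes pooled over samples.

    Sizes are processed in ascending order; a new bin starts whenever the
    gap to the previous size exceeds `gap` (so chains of closely spaced
    peaks share one bin).  Bin center = mean member size; per-sample
    areas are summed into the bins, absent entries are 0.
    """
    if gap < 0:
        raise ValueError("gap must be non-negative")
    profiles = list(profiles)
    samples = []
    for p in profiles:
        if p.sample_id not in samples:
            samples.append(p.sample_id)
    pooled = [
        (size, p.sample_id, area)
        for p in profiles
        for size, area in zip(p.sizes, p.areas)
    ]
    if not pooled:
        return BinTable(pd.DataFrame(index=pd.Index([], name="bin_bp"), columns=samples, dtype=float),
                        enzyme, dye)
    pooled.sort(key=lambda t: t[0])
    clusters, current = [], [pooled[0]]
    for entry in pooled[1:]:
        if entry[0] - current[-1][0] > gap:
            clusters.append(current)
            current = [entry]
        else:
            current.append(entry)
    clusters.append(current)
    centers = [float(np.mean([e[0] for e in c])) for c in clusters]
    data = np.zeros((len(clusters), len(samples)))
    col = {s: j for j, s in enumerate(samples)}
    for i, c in enumerate(clusters):
        for _, sid, area in c:
            data[i, col[sid]] += area
    table = pd.DataFrame(data, index=pd.Index(centers, name="bin_bp"), columns=samples)
    return BinTable(table, enzyme, dye)


# ---------------------------------------------------------------------------
# IO: delimited peak tables (sample_id, enzyme, dye, replicate, size_bp, area)

def write_peak_table(profiles, path: str | Path, comment: str = "") -> None:
    rows = [
        {
            "sample_id": p.sample_id,
            "enzyme": p.enzyme,
            "dye": p.dye,
            "replicate": p.replicate,
            "size_bp": s,
            "area": a,
        }
        for p in profiles
        for s, a in zip(p.sizes, p.areas)
    ]
    df = pd.DataFrame(rows, columns=["sample_id", "enzyme", "dye", "replicate", "size_bp", "area"])
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_peak_table(path: str | Path) -> list[PeakProfile]:
    df = pd.read_csv(path, sep="\t", comment="#")
    profiles = []
    for (sid, enz, dye, rep), grp in df.groupby(
        ["sample_id", "enzyme", "dye", "replicate"], sort=False
    ):
        profiles.append(
            PeakProfile(str(sid), str(enz), str(dye), int(rep),
                        grp["size_bp"].to_numpy(), grp["area"].to_numpy())
        )
    return profiles
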