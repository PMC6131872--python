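"""Localizing intragenomic phylogenetic conflict.

Given per-site log-likelihoods of one alignment under two competing
topologies, the per-site difference Delta-lnL is summed in overlapping
sliding windows (default 5,000 columns, step 100) along the genome; runs of
windows that deviate strongly and with a consistent sign from the
genome-wide background are called as conflict regions — contiguous tracts
whose phylogenetic signal favors the other topology.

The calling rule: window sums are centered at their median, and maximal
runs of at least ``min_run`` consecutive windows whose centered values
share sign and exceed ``mad_k`` times the median absolute deviation are
merged into regions.  Centering makes the rule well behaved when the whole
genome leans toward one topology; the MAD gives a robust scale that the
conflict region itself cannot inflate much.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .alignment import Alignment
from .treelik import SiteLikelihoodProfile

__all__ = [
    "DeltaProfile",
    "WindowScan",
    "ConflictRegion",
    "delta_profile",
    "window_scan",
    "call_regions",
    "split_alignment",
]


@dataclass
class DeltaProfile:
    """Per-site lnL(topology1) - lnL(topology2)."""

    delta: np.ndarray
    topology1: str = "T1"
    topology2: str = "T2"

    @property
    def total(self) -> float:
        return float(self.delta.sum())

    def __len__(self) -> int:
        return len(self.delta)


def delta_profile(
    p1: SiteLikelihoodProfile, p2: SiteLikelihoodProfile
) -> DeltaProfile:
    """Elementwise site-lnL difference, positive where topology 1 is favored."""
    if len(p1) != len(p2):
        raise ValueError("profiles computed on different alignment lengths")
    return DeltaProfile(
        delta=p1.site_lnl - p2.site_lnl,
        topology1=p1.topology_id or "T1",
        topology2=p2.topology_id or "T2",
    )


@dataclass
class WindowScan:
    """Sliding-window sums of the Delta-lnL profile.

    ``starts``/``ends`` are 1-based inclusive alignment columns; every
    window has exactly ``window_size`` columns (the trailing partial window
    is dropped).
    """

    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray
    window_size: int
    step: int
    topology1: str = "T1"
    topology2: str = "T2"

    def __len__(self) -> int:
        return len(self.values)

    def to_tsv(self) -> str:
        lines = ["start\tend\tsum_delta"]
        for s, e, v in zip(self.starts, self.ends, self.values):
            lines.append(f"{s}\t{e}\t{v:.6f}")
        return "\n".join(lines) + "\n"


def window_scan(
    delta: DeltaProfile, window_size: int = 5000, step: int = 100
) -> WindowScan:
    """Sum the site-lnL differences in sliding windows along the alignment."""
    L = len(delta)
    if window_size > L:
        raise ValueError("window_size exceeds alignment length")
    if window_size < 1 or step < 1:
        raise ValueError("window_size and step must be positive")
    cs = np.concatenate([[0.0], np.cumsum(delta.delta)])
    starts0 = np.arange(0, L - window_size + 1, step)
    values = cs[starts0 + window_size] - cs[starts0]
    return WindowScan(
        starts=starts0 + 1,
        ends=starts0 + window_size,
        values=values,
        window_size=window_size,
        step=step,
        topology1=delta.topology1,
        topology2=delta.topology2,
    )


@dataclass
class ConflictRegion:
    """A contiguous tract of windows favoring one topology.

    ``start``/``end`` are 1-based inclusive alignment columns spanning the
    *centers* of the first and last qualifying windows; a window's sum is
    attributed to its midpoint, so these boundaries track the underlying
    signal edge to within half a window regardless of how far the flagged
    run's outermost windows reach.  ``span_start``/``span_end`` give the
    union of the qualifying window spans.  ``direction`` names the favored
    topology; ``sum_delta`` is the summed per-window deviation over the run
    and ``n_windows`` the run length.
    """

    start: int
    end: int
    direction: str
    sum_delta: float
    n_windows: int
    span_start: int = 0
    span_end: int = 0
    source_start: int | None = None
    source_end: int | None = None


def call_regions(
    scan: WindowScan,
    min_run: int = 10,
    mad_k: float = 3.0,
    min_span: int | None = None,
    aln: Alignment | None = None,
) -> list[ConflictRegion]:
    """Call conflict regions from a window scan.

    Deterministic: windows are flagged when their median-centered value
    exceeds ``mad_k`` times the MAD of all window values; maximal runs of at
    least ``min_run`` consecutive same-sign flagged windows whose window
    *starts* span at least ``min_span`` columns (default: one window size)
    become regions.  The span requirement is structural: any anomaly
    confined to less than one window's worth of sequence smears across up
    to window_size/step consecutive overlapping windows purely by
    arithmetic, so a run qualifying as a *region* must be sustained over
    more than a single window of sequence.  When ``aln`` carries a
    source-coordinate map, regions also report un-trimmed coordinates.
    """
    if len(scan) == 0:
        raise ValueError("empty scan")
    if min_span is None:
        min_span = scan.window_size
    v = scan.values
    center = np.median(v)
    dev = v - center
    mad = np.median(np.abs(dev))
    if mad == 0.0:
        mad = np.mean(np.abs(dev)) or np.inf
    hot = np.abs(dev) > mad_k * mad
    sign = np.sign(dev)
    regions: list[ConflictRegion] = []
    i, n = 0, len(v)
    while i < n:
        if not hot[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and hot[j + 1] and sign[j + 1] == sign[i]:
            j += 1
        run_span = int(scan.starts[j] - scan.starts[i]) + 1
        if j - i + 1 >= min_run and run_span >= min_span:
            half = scan.window_size // 2
            direction = scan.topology1 if sign[i] > 0 else scan.topology2
            regions.append(
                ConflictRegion(
                    start=int(scan.starts[i]) + half,
                    end=int(scan.starts[j]) + half,
                    direction=direction,
                    sum_delta=float(dev[i : j + 1].sum()),
                    n_windows=j - i + 1,
                    span_start=int(scan.starts[i]),
                    span_end=int(scan.ends[j]),
                )
            )
        i = j + 1
    if aln is not None and aln.coords is not None:
        for r in regions:
            r.source_start = int(aln.coords[r.start - 1])
            r.source_end = int(aln.coords[r.end - 1])
    return regions


def regions_to_bed(regions: list[ConflictRegion], name: str = "scan") -> str:
    """Regions as BED (0-based half-open; name column = favored topology)."""
    lines = [
        f"{name}\t{r.start - 1}\t{r.end}\t{r.direction}\t{r.n_windows}"
        for r in regions
    ]
    return "\n".join(lines) + ("\n" if lines else "")


def split_alignment(
    aln: Alignment, regions
) -> tuple[Alignment, Alignment]:
    """Split columns into (inside regions, outside regions).

    ``regions`` is a list of :class:`ConflictRegion` or ``(start, end)``
    1-based inclusive column intervals.  Overlapping intervals are merged
    with a warning.  Both halves preserve column order and source
    coordinates; together they cover the original columns exactly.
    """
    intervals = []
    for r in regions:
        s, e = (r.start, r.end) if isinstance(r, ConflictRegion) else r
        if s < 1 or e > aln.n_columns or e < s:
            raise ValueError(f"region ({s}, {e}) outside alignment")
        intervals.append((s, e))
    intervals.sort()
    merged = []
    for s, e in intervals:
        if merged and s <= merged[-1][1] + 1:
            if s <= merged[-1][1]:
                warnings.warn("overlapping regions merged", RuntimeWarning)
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    mask = np.zeros(aln.n_columns, dtype=bool)
    for s, e in merged:
        mask[s - 1 : e] = True
    if mask.all():
        warnings.warn("regions cover the whole alignment; outside is empty",
                      RuntimeWarning)
    inside = aln.take_columns(np.nonzero(mask)[0])
    outside = aln.take_columns(np.nonzero(~mask)[0])
    return inside, outside
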