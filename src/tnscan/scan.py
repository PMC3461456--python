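"""Poisson scan statistics for Common Insertion Site (CIS) detection.

Insertions are modelled as uniform events on the genome.  For a window of
size w out of N total events on a genome of size G, the expected count is
u = N / (G / w).  Candidate windows are anchored at insertion positions,
so a window containing x events arises by chance with probability
P(X >= x - 1 | u): the anchoring insertion is given, and the Poisson upper
tail measures how surprising the x - 1 events *joining* it are.  The
p-value is Bonferroni-corrected by the total number of windows examined —
one window per insertion per window size scanned.  (Scoring the anchored
window with the unconditional tail P(X >= x) per size would understate
the false-positive rate by a factor ~x/u and call spurious CISs on
uniform random data; the correction here reproduces the expected clean
null at alpha = 0.05.)

Three event-counting schemes score each window, each testing its own null:

* insert  — distinct insertion events (library, 100-bp bin, orientation);
* library — distinct contributing libraries (robust to local hopping);
* region  — distinct occupied 100-bp bins (robust to the many-libraries-
  one-TA artifact from false priming or barcode misassignment).

A strong CIS is significant under all three; the default report requires
all three corrected p-values below alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as _sps

from .config import ScanConfig
from .events import InsertionEvent

INSERT, LIBRARY, REGION = "insert", "library", "region"
COUNT_MODES = (INSERT, LIBRARY, REGION)


def poisson_upper_tail(x: int, u: float) -> float:
    """P(X >= x) for X ~ Poisson(u); x = 0 returns 1."""
    if u <= 0:
        raise ValueError("u must be positive")
    if x <= 0:
        return 1.0
    return float(_sps.poisson.sf(x - 1, u))


def anchored_window_p(x: int, u: float) -> float:
    """Raw p-value of an insertion-anchored window holding x events.

    The window exists because of its anchoring insertion, so the tail is
    taken over the x - 1 events that joined it: P(X >= x - 1 | u).
    """
    return poisson_upper_tail(x - 1, u)


def bonferroni_correct(p: float, n_windows: int) -> float:
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    return min(1.0, p * n_windows)


def determine_window_sizes(total_events: int, cfg: ScanConfig) -> list[int]:
    """Window-size plan for a dataset of `total_events` insertions.

    For each integer event count k, the largest window w on the grid
    [w_min, w_max] (step w_step) is found such that k events in w is
    significant after Bonferroni correction by total_events; the distinct
    maxima, collected in decreasing size order, form the plan.  Outside
    2000..200000 events the six fixed default sizes are used.
    """
    if total_events < cfg.small_n or total_events > cfg.large_n:
        return sorted(cfg.default_windows, reverse=True)
    windows = np.arange(cfg.w_min, cfg.w_max + 1, cfg.w_step)
    u = total_events * windows / cfg.genome_size
    chosen: list[int] = []
    for k in range(2, 10_000):
        pk = _sps.poisson.sf(k - 2, u)  # anchored: tail over the k-1 joiners
        sig = np.minimum(1.0, pk * total_events) < cfg.alpha
        if not sig.any():
            continue
        w = int(windows[np.nonzero(sig)[0][-1]])
        if not chosen or w != chosen[0]:
            chosen.insert(0, w)
        if w == cfg.w_max:
            break
    return sorted(chosen, reverse=True)


@dataclass(frozen=True)
class CandidateWindow:
    chrom: str
    start: int
    end: int
    window_size: int
    event_count: int
    p_raw: float
    p_corrected: float


@dataclass(frozen=True)
class CIS:
    """A called Common Insertion Site with its three corrected p-values."""

    chrom: str
    start: int
    end: int
    window_size: int
    insert_count: int
    library_count: int
    region_count: int
    p_insert: float
    p_library: float
    p_region: float
    libraries: tuple[str, ...]
    n_pos_strand: int
    annotation: str = ""


def _mode_totals(events: Sequence[InsertionEvent]) -> dict[str, int]:
    """Genome-wide event totals feeding u for each counting scheme.

    Insert and library modes use the total insertion-event count (the
    insert total bounds library events, keeping the library test
    conservative); region mode uses the total number of distinct occupied
    bins.
    """
    insert_total = len(events)
    region_total = len({(e.chrom, e.bin_index) for e in events})
    return {INSERT: insert_total, LIBRARY: insert_total, REGION: region_total}


def count_events(window: tuple[str, int, int], events: Iterable[InsertionEvent],
                 count_mode: str = INSERT) -> int:
    """Count events inside [start, end) of one window under a scheme.

    An event is inside when its bin start falls within the window.
    """
    chrom, start, end = window
    inside = [e for e in events
              if e.chrom == chrom and start <= e.bin_start < end]
    if count_mode == INSERT:
        return len(inside)
    if count_mode == LIBRARY:
        return len({e.library for e in inside})
    if count_mode == REGION:
        return len({e.bin_index for e in inside})
    raise ValueError(f"unknown count_mode {count_mode!r}")


def _min_significant_count(u: float, n_corr: int, alpha: float) -> int:
    k = 2
    while bonferroni_correct(anchored_window_p(k, u), n_corr) >= alpha:
        k += 1
        if k > 10_000_000:  # pragma: no cover
            raise RuntimeError("no significant count found")
    return k


def find_peaks(events: Sequence[InsertionEvent], window_size: int,
               cfg: ScanConfig, count_mode: str = INSERT,
               n_windows: int | None = None) -> list[CandidateWindow]:
    """Significant non-overlapping peak windows at one window size.

    Candidate windows are anchored at every insertion position (left edge
    on the event's bin start).  A greedy loop repeatedly selects the
    remaining window with the highest count (ties: lowest chromosome order
    then start), discarding every window overlapping it; selected windows
    with corrected p < alpha are emitted.

    `n_windows` is the Bonferroni multiplier (total windows examined);
    it defaults to the insertion count (one anchored window per insertion
    at this size) and is raised to insertions x sizes by the full scan.

    Windows whose count cannot reach significance are pruned before the
    loop: at fixed window size significance is monotone in the count, so
    they can neither be emitted nor outrank a significant window.
    """
    if not events:
        return []
    totals = _mode_totals(events)
    insert_total = totals[INSERT]
    if n_windows is None:
        n_windows = insert_total
    u = totals[count_mode] * window_size / cfg.genome_size
    k_min = _min_significant_count(u, n_windows, cfg.alpha)

    chrom_order = {c: i for i, c in enumerate(dict.fromkeys(e.chrom for e in events))}
    by_chrom: dict[str, list[InsertionEvent]] = {}
    for e in sorted(events, key=lambda e: (chrom_order[e.chrom], e.bin_start)):
        by_chrom.setdefault(e.chrom, []).append(e)

    candidates: list[tuple[int, int, str, int]] = []  # (count, chrom_idx, chrom, start)
    for chrom, evs in by_chrom.items():
        starts = [e.bin_start for e in evs]
        anchors = sorted(set(starts))
        # sliding window with per-key multiplicity for distinct counting
        lo = hi = 0
        keys: dict = {}
        for a in anchors:
            while hi < len(evs) and starts[hi] < a + window_size:
                k = _mode_key(evs[hi], count_mode)
                keys[k] = keys.get(k, 0) + 1
                hi += 1
            while lo < len(evs) and starts[lo] < a:
                k = _mode_key(evs[lo], count_mode)
                keys[k] -= 1
                if keys[k] == 0:
                    del keys[k]
                lo += 1
            count = len(keys)
            if count >= k_min:
                candidates.append((count, chrom_order[chrom], chrom, a))

    candidates.sort(key=lambda c: (-c[0], c[1], c[3]))
    selected: list[CandidateWindow] = []
    taken: dict[str, list[tuple[int, int]]] = {}
    for count, _, chrom, start in candidates:
        end = start + window_size
        if any(start < e0 and s0 < end for s0, e0 in taken.get(chrom, ())):
            continue
        p_raw = anchored_window_p(count, u)
        p_corr = bonferroni_correct(p_raw, n_windows)
        if p_corr < cfg.alpha:
            selected.append(CandidateWindow(chrom, start, end, window_size,
                                            count, p_raw, p_corr))
        taken.setdefault(chrom, []).append((start, end))
    selected.sort(key=lambda w: (chrom_order[w.chrom], w.start))
    return selected


def _mode_key(e: InsertionEvent, count_mode: str):
    if count_mode == INSERT:
        return (e.library, e.bin_index, e.orientation)
    if count_mode == LIBRARY:
        return e.library
    if count_mode == REGION:
        return e.bin_index
    raise ValueError(f"unknown count_mode {count_mode!r}")


def resolve_across_window_sizes(candidates: Sequence[CandidateWindow]) -> list[CandidateWindow]:
    """Minimal non-overlapping set across window sizes, most significant first.

    Greedy by ascending raw p-value; on an exact tie the larger window
    wins, then the lower genomic coordinate for determinism.
    """
    order = sorted(candidates,
                   key=lambda w: (w.p_raw, -w.window_size, w.chrom, w.start))
    selected: list[CandidateWindow] = []
    taken: dict[str, list[tuple[int, int]]] = {}
    for w in order:
        if any(w.start < e0 and s0 < w.end for s0, e0 in taken.get(w.chrom, ())):
            continue
        selected.append(w)
        taken.setdefault(w.chrom, []).append((w.start, w.end))
    selected.sort(key=lambda w: (w.chrom, w.start))
    return selected


def score_window(window: tuple[str, int, int], window_size: int,
                 events: Sequence[InsertionEvent], cfg: ScanConfig,
                 n_windows: int | None = None) -> CIS:
    """Recompute all three corrected p-values for a final window."""
    chrom, start, end = window
    inside = [e for e in events if e.chrom == chrom and start <= e.bin_start < end]
    totals = _mode_totals(events)
    if n_windows is None:
        n_windows = totals[INSERT]
    counts = {}
    pvals = {}
    for mode in COUNT_MODES:
        counts[mode] = len({_mode_key(e, mode) for e in inside})
        u = totals[mode] * window_size / cfg.genome_size
        pvals[mode] = bonferroni_correct(anchored_window_p(counts[mode], u),
                                         n_windows)
    return CIS(
        chrom=chrom, start=start, end=end, window_size=window_size,
        insert_count=counts[INSERT], library_count=counts[LIBRARY],
        region_count=counts[REGION],
        p_insert=pvals[INSERT], p_library=pvals[LIBRARY], p_region=pvals[REGION],
        libraries=tuple(sorted({e.library for e in inside})),
        n_pos_strand=sum(1 for e in inside if e.orientation == "+"),
    )


def call_cis(events: Sequence[InsertionEvent], cfg: ScanConfig,
             require_all: bool = True) -> list[CIS]:
    """Full CIS scan: window plan, per-size peak finding on insert counts,
    cross-size resolution, and three-way scoring of each final window.

    With require_all (default) only CISs whose insert, library and region
    corrected p-values are all below alpha are reported, sorted by
    ascending region then insert p-value.
    """
    events = list(events)
    if not events:
        return []
    sizes = determine_window_sizes(len(events), cfg)
    n_windows = len(events) * max(1, len(sizes))  # total windows examined
    candidates: list[CandidateWindow] = []
    for w in sizes:
        candidates.extend(find_peaks(events, w, cfg, count_mode=INSERT,
                                     n_windows=n_windows))
    finals = resolve_across_window_sizes(candidates)
    cis_list = [score_window((w.chrom, w.start, w.end), w.window_size, events,
                             cfg, n_windows=n_windows)
                for w in finals]
    if require_all:
        cis_list = [c for c in cis_list
                    if c.p_insert < cfg.alpha and c.p_library < cfg.alpha
                    and c.p_region < cfg.alpha]
    cis_list.sort(key=lambda c: (c.p_region, c.p_insert, c.chrom, c.start))
    return cis_list
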