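"""Bulk-segregant locus mapping: frequencies, 10-SNP windows, 95% fixation.

The mapping statistic is deliberately simple and mirrors standard BSA-seq
practice on near-fixed pools: per-SNP 3S allele frequencies are averaged in
running windows of 10 consecutive informative SNPs (step one SNP), and
maximal runs of windows whose mean is at or above 95% (3S-fixed) or at or
below 5% (BY-fixed) are reported as loci.  The interval of a locus is the
smallest region spanned by its qualifying windows.  Engineered lesions
(ira2Δ2933, sfl1Δ) are detected from their dedicated mutant-read fraction
and reported as MUTANT loci, which is how a lesion remains mappable even
where the surrounding SNPs do not segregate in a given backcross.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cross import Haplotype
from .markers import ENGINEERED_GENES, MarkerMap
from .pools import AlleleCountTable


@dataclass(frozen=True)
class MappingParams:
    """Locus-calling parameters.

    ``merge_gap_cm``: runs of same-sign qualifying windows separated by
    less than this genetic distance are one locus.  Around a fixed site
    the expected linked-marker frequency decays as 1 - r (Haldane),
    crossing 95% near 5 cM and 90% near 11 cM; with pools of tens of
    segregants the realized frequency has a sampling SD of 0.03-0.06, so
    threshold excursions occur throughout the ~10 cM belt where the
    expectation is within ~2 SD of the threshold.  Runs interrupted
    inside that belt are shoulder noise around one locus, not two loci.
    """

    window_snps: int = 10
    fix_threshold: float = 0.95
    min_depth: int = 1
    merge_gap_cm: float = 10.0

    def __post_init__(self) -> None:
        if self.window_snps < 1:
            raise ValueError("window_snps must be >= 1")
        if not 0.5 < self.fix_threshold <= 1.0:
            raise ValueError("fix_threshold must lie in (0.5, 1]")
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")
        if self.merge_gap_cm < 0:
            raise ValueError("merge_gap_cm must be >= 0")


@dataclass
class FrequencyTrack:
    """Per-marker 3S frequency (NaN = missing) plus engineered-site info."""

    map: MarkerMap
    values: np.ndarray
    mutant_frac: dict[str, float] = field(default_factory=dict)
    engineered_segregating: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.map.n_markers,):
            raise ValueError("track must have one value per marker")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("frequencies must lie in [0, 1]")
        for gene in self.mutant_frac:
            self.engineered_segregating.setdefault(gene, True)

    def masked(self, informative: np.ndarray,
               engineered_segregating: Mapping[str, bool] | None = None,
               ) -> "FrequencyTrack":
        """Blank out markers that do not segregate in the analysed cross."""
        values = np.where(np.asarray(informative, dtype=bool), self.values, np.nan)
        eng = dict(self.engineered_segregating)
        if engineered_segregating:
            eng.update(engineered_segregating)
        return FrequencyTrack(self.map, values, dict(self.mutant_frac), eng)


def frequencies_from_counts(table: AlleleCountTable,
                            params: MappingParams = MappingParams()) -> FrequencyTrack:
    """3S frequency = count_3s / (count_by + count_3s); ``count_other`` is
    excluded from the denominator; markers below ``min_depth`` informative
    reads are missing."""
    informative = table.count_by + table.count_3s
    ok = informative >= max(params.min_depth, 1)
    values = np.full(table.map.n_markers, np.nan)
    values[ok] = table.count_3s[ok] / informative[ok]
    mutant_frac = {gene: count / depth
                   for gene, (count, depth) in table.mutant.items() if depth > 0}
    return FrequencyTrack(table.map, values, mutant_frac)


@dataclass
class WindowTrack:
    """Sliding-window means over consecutive informative markers.

    ``first``/``last`` are global marker indices of each window's outermost
    members; ``member_idx`` lists all informative marker indices per
    chromosome so interval delimitation can recover window membership.
    """

    map: MarkerMap
    chrom: np.ndarray          # chromosome label per window
    first: np.ndarray          # global index of first member marker
    last: np.ndarray           # global index of last member marker
    mean: np.ndarray
    track: FrequencyTrack

    def __len__(self) -> int:
        return len(self.mean)


def sliding_windows(track: FrequencyTrack,
                    marker_map: MarkerMap | None = None,
                    params: MappingParams = MappingParams()) -> WindowTrack:
    """Window means of ``window_snps`` consecutive informative markers,
    step one marker, never spanning a chromosome boundary."""
    marker_map = marker_map or track.map
    w = params.window_snps
    chroms, firsts, lasts, means = [], [], [], []
    for chrom, block in marker_map.chrom_slices.items():
        idx = np.arange(block.start, block.stop)
        idx = idx[np.isfinite(track.values[idx])]
        if idx.size < w:
            continue
        vals = track.values[idx]
        csum = np.concatenate([[0.0], np.cumsum(vals)])
        win_means = (csum[w:] - csum[:-w]) / w
        n_win = idx.size - w + 1
        chroms.extend([chrom] * n_win)
        firsts.append(idx[:n_win])
        lasts.append(idx[w - 1:])
        means.append(win_means)
    if not means:
        empty = np.empty(0)
        return WindowTrack(marker_map, np.array(chroms, dtype=object),
                           empty.astype(int), empty.astype(int), empty, track)
    return WindowTrack(marker_map, np.array(chroms, dtype=object),
                       np.concatenate(firsts), np.concatenate(lasts),
                       np.concatenate(means), track)


@dataclass
class LocusCall:
    """A fixed-allele interval called from the windowed track."""

    chrom: str
    start_bp: int              # 1-based inclusive
    end_bp: int
    fixed_allele: str          # BY, 3S, or MUTANT
    mean_freq: float           # frequency of the fixed allele over members
    first_idx: int             # global marker index span
    last_idx: int
    n_markers: int = 0

    def contains_marker(self, idx: int) -> bool:
        return self.first_idx <= idx <= self.last_idx

    def genes(self, marker_map: MarkerMap) -> list[str]:
        return sorted(g for g, i in marker_map.causal_index.items()
                      if self.contains_marker(i))


def _window_states(windowed: WindowTrack, params: MappingParams) -> np.ndarray:
    state = np.zeros(len(windowed), dtype=int)
    state[windowed.mean >= params.fix_threshold] = 1      # 3S-fixed
    state[windowed.mean <= 1.0 - params.fix_threshold] = -1   # BY-fixed
    return state


def call_fixed_loci(windowed: WindowTrack,
                    marker_map: MarkerMap | None = None,
                    params: MappingParams = MappingParams()) -> list[LocusCall]:
    """Maximal runs of qualifying windows -> loci; engineered lesions with a
    fixed mutant fraction are promoted to (or emitted as) MUTANT calls."""
    marker_map = marker_map or windowed.map
    track = windowed.track
    state = _window_states(windowed, params)
    calls: list[LocusCall] = []
    i = 0
    while i < len(windowed):
        s = state[i]
        if s == 0:
            i += 1
            continue
        j = i
        while (j + 1 < len(windowed) and state[j + 1] == s
               and windowed.chrom[j + 1] == windowed.chrom[i]):
            j += 1
        first = int(windowed.first[i])
        last = int(windowed.last[j])
        member = np.arange(first, last + 1)
        member = member[np.isfinite(track.values[member])]
        mean_3s = float(track.values[member].mean())
        allele = "3S" if s == 1 else "BY"
        mean_freq = mean_3s if s == 1 else 1.0 - mean_3s
        calls.append(LocusCall(str(windowed.chrom[i]), int(marker_map.pos_bp[first]),
                               int(marker_map.pos_bp[last]), allele, mean_freq,
                               first, last, n_markers=member.size))
        i = j + 1

    # Same-sign runs within one recombination footprint of each other are
    # shoulder noise around a single fixed site, not two loci.
    calls = _merge_nearby_runs(calls, track, marker_map, params)

    # Engineered lesions: fixed mutant fraction -> MUTANT allele category.
    for gene in ENGINEERED_GENES:
        frac = track.mutant_frac.get(gene)
        if frac is None or not track.engineered_segregating.get(gene, True):
            continue
        if frac < params.fix_threshold:
            continue
        idx = marker_map.causal_index.get(gene)
        if idx is None:
            continue
        covering = [c for c in calls if c.chrom == marker_map.chrom[idx]
                    and c.contains_marker(idx)]
        if covering:
            for c in covering:
                c.fixed_allele = "MUTANT"
                c.mean_freq = max(c.mean_freq, frac)
        else:
            calls.append(LocusCall(str(marker_map.chrom[idx]),
                                   int(marker_map.pos_bp[idx]),
                                   int(marker_map.pos_bp[idx]),
                                   "MUTANT", frac, idx, idx, n_markers=1))
    calls.sort(key=lambda c: (list(marker_map.chrom_slices).index(c.chrom), c.start_bp))
    return calls


def _merge_nearby_runs(calls: list[LocusCall], track: FrequencyTrack,
                       marker_map: MarkerMap,
                       params: MappingParams) -> list[LocusCall]:
    merged: list[LocusCall] = []
    for c in sorted(calls, key=lambda c: (c.chrom, c.first_idx)):
        prev = merged[-1] if merged else None
        if (prev is not None and prev.chrom == c.chrom
                and prev.fixed_allele == c.fixed_allele
                and (c.first_idx <= prev.last_idx + 1
                     or marker_map.pos_cM[c.first_idx] - marker_map.pos_cM[prev.last_idx]
                     <= params.merge_gap_cm)):
            first, last = prev.first_idx, max(prev.last_idx, c.last_idx)
            member = np.arange(first, last + 1)
            member = member[np.isfinite(track.values[member])]
            mean_3s = float(track.values[member].mean())
            mean_freq = mean_3s if c.fixed_allele == "3S" else 1.0 - mean_3s
            merged[-1] = replace(prev, end_bp=max(prev.end_bp, c.end_bp),
                                 last_idx=last, mean_freq=mean_freq,
                                 n_markers=member.size)
        else:
            merged.append(c)
    return merged


def delimit_interval(locus: LocusCall,
                     windowed: WindowTrack,
                     marker_map: MarkerMap | None = None,
                     params: MappingParams = MappingParams()) -> LocusCall:
    """Trim a locus to the smallest region spanned by qualifying windows.

    The interval runs from the first to the last marker belonging to any
    window whose mean crosses the threshold on the locus's side and whose
    span intersects the locus.
    """
    marker_map = marker_map or windowed.map
    if locus.fixed_allele == "MUTANT" and locus.first_idx == locus.last_idx:
        return replace(locus)   # single-marker engineered-site call
    state = _window_states(windowed, params)
    side = -1 if locus.fixed_allele == "BY" else 1
    hit = ((state == side)
           & (np.asarray(windowed.chrom) == locus.chrom)
           & (windowed.first <= locus.last_idx)
           & (windowed.last >= locus.first_idx))
    if not hit.any():
        raise ValueError("locus has no qualifying window in this window track")
    first = int(windowed.first[hit].min())
    last = int(windowed.last[hit].max())
    return replace(locus, start_bp=int(marker_map.pos_bp[first]),
                   end_bp=int(marker_map.pos_bp[last]),
                   first_idx=first, last_idx=last)


def map_pool(table: AlleleCountTable,
             params: MappingParams = MappingParams(),
             informative: np.ndarray | None = None,
             engineered_segregating: Mapping[str, bool] | None = None,
             ) -> list[LocusCall]:
    """Counts -> frequencies -> windows -> delimited locus calls for one pool."""
    track = frequencies_from_counts(table, params)
    if informative is not None or engineered_segregating:
        mask = informative if informative is not None \
            else np.ones(table.map.n_markers, dtype=bool)
        track = track.masked(mask, engineered_segregating)
    windowed = sliding_windows(track, table.map, params)
    # call_fixed_loci already reports each run's smallest qualifying span,
    # so calls come out delimited.
    return call_fixed_loci(windowed, table.map, params)


def calls_to_frame(calls: Sequence[LocusCall], marker_map: MarkerMap,
                   pool: str = "") -> pd.DataFrame:
    rows = [{
        "chrom": c.chrom, "start_bp": c.start_bp, "end_bp": c.end_bp,
        "fixed_allele": c.fixed_allele, "mean_freq": round(c.mean_freq, 6),
        "n_markers": c.n_markers, "pool": pool,
        "genes": ",".join(c.genes(marker_map)),
    } for c in calls]
    return pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "fixed_allele",
                                       "mean_freq", "n_markers", "pool", "genes"])


def map_backcross_pools(
    pool_by: AlleleCountTable,
    pool_3s: AlleleCountTable,
    marker_map: MarkerMap | None = None,
    params: MappingParams = MappingParams(),
    founder: Haplotype | None = None,
) -> pd.DataFrame:
    """Call loci in reciprocal backcross pools and merge them into one report.

    When the founder segregant is supplied, markers where it matches the
    recurrent parent are masked as uninformative (they cannot segregate in
    that backcross), and an engineered lesion is considered mappable only
    where it segregates.  The merged report is unioned by causal-site
    overlap: each causal site covered by a call in either pool yields one
    locus (interval = intersection when both pools call it, provenance
    ``BY+3S``; otherwise the single pool's interval and label).  A call
    spanning two causal sites — possible on a scaled map where linked
    fixed loci leave no sub-threshold valley between them — therefore
    still reports each site as its own locus.  Calls covering no causal
    site are appended with an empty ``genes`` field.
    """
    marker_map = marker_map or pool_by.map
    if pool_by.map is not pool_3s.map and pool_by.map.n_markers != pool_3s.map.n_markers:
        raise ValueError("the two pools were counted on different marker maps")

    kwargs_by: dict = {}
    kwargs_3s: dict = {}
    if founder is not None:
        eng = {"IRA2": founder.ira2_state == "D2933",
               "SFL1": founder.sfl1_state == "DELETED"}
        kwargs_by = dict(informative=founder.origins == 1,    # founder 3S vs recurrent BY
                         engineered_segregating=eng)
        kwargs_3s = dict(informative=founder.origins == 0,    # founder BY vs recurrent 3S
                         engineered_segregating=eng)
    calls_by = map_pool(pool_by, params, **kwargs_by)
    calls_3s = map_pool(pool_3s, params, **kwargs_3s)

    rows: list[dict] = []
    assigned_by: set[int] = set()
    assigned_3s: set[int] = set()
    for gene, idx in marker_map.causal_index.items():
        hit_by = [(k, c) for k, c in enumerate(calls_by) if c.contains_marker(idx)]
        hit_3s = [(k, c) for k, c in enumerate(calls_3s) if c.contains_marker(idx)]
        if not hit_by and not hit_3s:
            continue
        assigned_by.update(k for k, _ in hit_by)
        assigned_3s.update(k for k, _ in hit_3s)
        hits = [c for _, c in hit_by] + [c for _, c in hit_3s]
        first = max(c.first_idx for c in hits)
        last = min(c.last_idx for c in hits)
        allele = "MUTANT" if any(c.fixed_allele == "MUTANT" for c in hits) \
            else hits[0].fixed_allele
        pool = "BY+3S" if hit_by and hit_3s else ("BY" if hit_by else "3S")
        rows.append({"chrom": hits[0].chrom,
                     "start_bp": int(marker_map.pos_bp[first]),
                     "end_bp": int(marker_map.pos_bp[last]),
                     "fixed_allele": allele,
                     "mean_freq": round(max(c.mean_freq for c in hits), 6),
                     "n_markers": last - first + 1, "pool": pool, "genes": gene})
    for k, c in enumerate(calls_by):
        if k not in assigned_by:
            rows.append(_call_row(c, marker_map, "BY"))
    for k, c in enumerate(calls_3s):
        if k not in assigned_3s:
            rows.append(_call_row(c, marker_map, "3S"))

    df = pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "fixed_allele",
                                     "mean_freq", "n_markers", "pool", "genes"])
    chrom_order = {c: i for i, c in enumerate(marker_map.chrom_slices)}
    return df.sort_values(["chrom", "start_bp"],
                          key=lambda s: s.map(chrom_order) if s.name == "chrom" else s
                          ).reset_index(drop=True)


def _call_row(c: LocusCall, marker_map: MarkerMap, pool: str) -> dict:
    return {"chrom": c.chrom, "start_bp": c.start_bp, "end_bp": c.end_bp,
            "fixed_allele": c.fixed_allele, "mean_freq": round(c.mean_freq, 6),
            "n_markers": c.n_markers, "pool": pool,
            "genes": ",".join(c.genes(marker_map))}
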