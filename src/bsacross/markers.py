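"""Biallelic SNP marker maps for the BY x 3S yeast cross.

A :class:`MarkerMap` holds an ordered set of biallelic SNPs across the 16
*S. cerevisiae* chromosomes, each with a physical (bp) and genetic (cM)
coordinate and the two parental alleles (lab strain BY4716, clinical isolate
322134S, "3S").  A handful of markers are flagged as *causal sites*: the six
cryptic-variant genes (END3, FLO8, MGA1, MSS11, SFL1, TRR1) plus IRA2, the
gene whose spontaneous ira2Δ2933 lesion acts as a phenotypic capacitor.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Roman-numeral chromosome labels in karyotype order.
CHROMOSOMES: tuple[str, ...] = (
    "I", "II", "III", "IV", "V", "VI", "VII", "VIII",
    "IX", "X", "XI", "XII", "XIII", "XIV", "XV", "XVI",
)

#: S288c reference chromosome lengths in bp (sacCer3).
CHROM_LENGTHS_BP: dict[str, int] = {
    "I": 230218, "II": 813184, "III": 316620, "IV": 1531933,
    "V": 576874, "VI": 270161, "VII": 1090940, "VIII": 562643,
    "IX": 439888, "X": 745751, "XI": 666816, "XII": 1078177,
    "XIII": 924431, "XIV": 784333, "XV": 1091291, "XVI": 948066,
}

#: Number of high-confidence BY/3S SNPs in the real mapping data.
REFERENCE_SNP_COUNT = 36756

#: Yeast-typical genetic density; configurable everywhere it is used.
DEFAULT_CM_PER_KB = 0.4

#: The six genes whose cryptic BY/3S variants participate in the
#: higher-order interactions.
CRYPTIC_GENES: tuple[str, ...] = ("END3", "FLO8", "MGA1", "MSS11", "SFL1", "TRR1")

#: All causal sites tracked on a map (cryptic genes plus the capacitor IRA2).
CAUSAL_GENES: tuple[str, ...] = CRYPTIC_GENES + ("IRA2",)

#: Genes that can carry an engineered lesion segregating like an allele.
ENGINEERED_GENES: tuple[str, ...] = ("IRA2", "SFL1")

# Approximate native gene coordinates; TRR1's chromosome is configurable
# (default IV, its physical home).  Expressed against CHROM_LENGTHS_BP and
# rescaled proportionally when a map uses different chromosome lengths.
DEFAULT_CAUSAL_POSITIONS: dict[str, tuple[str, int]] = {
    "FLO8": ("V", 378500),
    "MGA1": ("VII", 988000),
    "MSS11": ("XIII", 590000),
    "END3": ("XIV", 470000),
    "IRA2": ("XV", 172000),
    "SFL1": ("XV", 588000),
    "TRR1": ("IV", 1181000),
}

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class Marker:
    """A single biallelic SNP."""

    id: str
    chrom: str
    pos_bp: int       # 1-based physical position
    pos_cM: float     # genetic position on its chromosome
    allele_by: str
    allele_3s: str

    def __post_init__(self) -> None:
        if self.pos_bp < 1:
            raise ValueError(f"marker {self.id}: pos_bp must be >= 1")
        if self.pos_cM < 0:
            raise ValueError(f"marker {self.id}: pos_cM must be >= 0")
        if self.allele_by == self.allele_3s:
            raise ValueError(f"marker {self.id}: parental alleles must differ")


class MarkerMap:
    """Ordered biallelic SNPs on 16 chromosomes plus named causal sites.

    Parameters
    ----------
    df
        One row per marker with columns ``id, chrom, pos_bp, pos_cM,
        allele_by, allele_3s``, grouped by chromosome in karyotype order
        and sorted by position within each chromosome.
    causal_sites
        Mapping of gene name to marker id; every gene must resolve to
        exactly one marker.
    """

    def __init__(self, df: pd.DataFrame, causal_sites: Mapping[str, str]):
        required = ["id", "chrom", "pos_bp", "pos_cM", "allele_by", "allele_3s"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"marker frame missing columns: {missing}")
        df = df.reset_index(drop=True)[required].copy()
        df["pos_bp"] = df["pos_bp"].astype(np.int64)
        df["pos_cM"] = df["pos_cM"].astype(float)

        if df["id"].duplicated().any():
            raise ValueError("marker ids must be unique")
        bad_chrom = set(df["chrom"]) - set(CHROMOSOMES)
        if bad_chrom:
            raise ValueError(f"unknown chromosome labels: {sorted(bad_chrom)}")

        # Chromosome blocks must be contiguous and in karyotype order.
        order = [c for c in CHROMOSOMES if c in set(df["chrom"])]
        blocks: dict[str, slice] = {}
        start = 0
        for chrom in order:
            rows = np.flatnonzero(df["chrom"].to_numpy() == chrom)
            if rows.size == 0:
                continue
            if rows[0] != start or not np.array_equal(rows, np.arange(rows[0], rows[-1] + 1)):
                raise ValueError("markers must be grouped by chromosome in karyotype order")
            blocks[chrom] = slice(rows[0], rows[-1] + 1)
            start = rows[-1] + 1
            bp = df["pos_bp"].to_numpy()[blocks[chrom]]
            if np.any(np.diff(bp) <= 0):
                raise ValueError(f"pos_bp must be strictly increasing on chromosome {chrom}")
            # non-decreasing only: a zero-recombination map is legal
            cm = df["pos_cM"].to_numpy()[blocks[chrom]]
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"pos_cM must be non-decreasing on chromosome {chrom}")
        if start != len(df):
            raise ValueError("markers must be grouped by chromosome in karyotype order")

        id_to_idx = {mid: i for i, mid in enumerate(df["id"])}
        causal_index: dict[str, int] = {}
        for gene, marker_id in causal_sites.items():
            if marker_id not in id_to_idx:
                raise ValueError(f"causal gene {gene} names unknown marker {marker_id!r}")
            causal_index[gene] = id_to_idx[marker_id]
        # Two genes may share a marker only on degenerate maps (e.g. a
        # single marker on their chromosome); builders reject explicit
        # duplicate placements before construction.

        self._df = df
        self.causal_sites: dict[str, str] = dict(causal_sites)
        self.causal_index: dict[str, int] = causal_index
        self.chrom_slices: dict[str, slice] = blocks
        self._id_to_idx = id_to_idx
        self.pos_bp: np.ndarray = df["pos_bp"].to_numpy()
        self.pos_cM: np.ndarray = df["pos_cM"].to_numpy()
        self.chrom: np.ndarray = df["chrom"].to_numpy()

    # -- basic accessors -------------------------------------------------
    @property
    def n_markers(self) -> int:
        return len(self._df)

    def __len__(self) -> int:
        return self.n_markers

    @property
    def chromosomes(self) -> list[str]:
        return list(self.chrom_slices)

    def marker(self, i: int) -> Marker:
        row = self._df.iloc[i]
        return Marker(row["id"], row["chrom"], int(row["pos_bp"]),
                      float(row["pos_cM"]), row["allele_by"], row["allele_3s"])

    def index_of(self, marker_id: str) -> int:
        return self._id_to_idx[marker_id]

    def marker_ids(self) -> pd.Series:
        return self._df["id"]

    def to_frame(self) -> pd.DataFrame:
        """Copy of the marker table, with a ``causal_gene`` annotation column."""
        df = self._df.copy()
        gene_at = {idx: gene for gene, idx in self.causal_index.items()}
        df["causal_gene"] = [gene_at.get(i, "") for i in range(len(df))]
        return df

    def __repr__(self) -> str:
        return (f"MarkerMap({self.n_markers} markers on "
                f"{len(self.chrom_slices)} chromosomes, "
                f"causal={sorted(self.causal_sites)})")


def _allocate_counts(n_markers: int, lengths: Sequence[int]) -> list[int]:
    """Largest-remainder apportionment with at least one marker per chromosome."""
    lengths = np.asarray(lengths, dtype=float)
    quota = n_markers * lengths / lengths.sum()
    counts = np.maximum(np.floor(quota).astype(int), 1)
    while counts.sum() > n_markers:
        counts[np.argmax(counts)] -= 1
    rema = quota - counts
    while counts.sum() < n_markers:
        i = int(np.argmax(rema))
        counts[i] += 1
        rema[i] = -np.inf
    return counts.tolist()


def build_marker_map(
    n_markers: int = REFERENCE_SNP_COUNT,
    chrom_lengths_bp: Mapping[str, int] | Sequence[int] | None = None,
    cm_per_kb: float = DEFAULT_CM_PER_KB,
    causal_overrides: Mapping[str, tuple[str, int]] | None = None,
    seed: int = 0,
) -> MarkerMap:
    """Build a random marker map with causal genes placed at fixed loci.

    Markers are spread across chromosomes proportionally to physical length
    (uniform positions, sorted), genetic positions follow a constant
    cM-per-kb density, and each causal gene is attached to the marker
    nearest its (possibly overridden) target coordinate.  Deterministic for
    a fixed seed.
    """
    if n_markers < len(CHROMOSOMES):
        raise ValueError("need at least one marker per chromosome (n_markers >= 16)")
    if cm_per_kb < 0:
        raise ValueError("cm_per_kb must be >= 0")
    if chrom_lengths_bp is None:
        lengths = dict(CHROM_LENGTHS_BP)
    elif isinstance(chrom_lengths_bp, Mapping):
        lengths = {c: int(chrom_lengths_bp[c]) for c in CHROMOSOMES}
    else:
        if len(chrom_lengths_bp) != 16:
            raise ValueError("chrom_lengths_bp must supply 16 lengths")
        lengths = dict(zip(CHROMOSOMES, (int(x) for x in chrom_lengths_bp)))
    if any(v <= 0 for v in lengths.values()):
        raise ValueError("chromosome lengths must be positive")

    rng = np.random.default_rng(seed)
    counts = _allocate_counts(n_markers, [lengths[c] for c in CHROMOSOMES])

    frames = []
    for chrom, k in zip(CHROMOSOMES, counts):
        L = lengths[chrom]
        k = min(k, L)
        pos = np.sort(rng.choice(L, size=k, replace=False)) + 1
        a0 = rng.integers(0, 4, size=k)
        a1 = (a0 + rng.integers(1, 4, size=k)) % 4
        frames.append(pd.DataFrame({
            "id": [f"{chrom}:{p}" for p in pos],
            "chrom": chrom,
            "pos_bp": pos,
            "pos_cM": (pos - 1) / 1000.0 * cm_per_kb,
            "allele_by": _BASES[a0],
            "allele_3s": _BASES[a1],
        }))
    df = pd.concat(frames, ignore_index=True)

    targets = dict(DEFAULT_CAUSAL_POSITIONS)
    if causal_overrides:
        for gene, (chrom, pos) in causal_overrides.items():
            targets[gene] = (chrom, int(pos))

    causal_sites: dict[str, str] = {}
    taken: dict[int, str] = {}
    id_col = df["id"].to_numpy()
    for gene in sorted(targets):
        chrom, pos = targets[gene]
        if causal_overrides and gene in causal_overrides:
            target_bp = pos
        else:
            # rescale the native coordinate to this map's chromosome length
            target_bp = pos * lengths[chrom] / CHROM_LENGTHS_BP[chrom]
        block = df.index[df["chrom"] == chrom]
        if len(block) == 0:
            raise ValueError(f"causal gene {gene}: chromosome {chrom} has no markers")
        positions = df.loc[block, "pos_bp"].to_numpy()
        order = np.argsort(np.abs(positions - target_bp))
        idx = int(block[order[0]])
        if idx in taken:
            if causal_overrides and gene in causal_overrides:
                raise ValueError(f"causal genes {taken[idx]} and {gene} both "
                                 f"placed at marker {id_col[idx]}")
            # default placement: fall back to the nearest free marker; on a
            # degenerate map with no free marker left, share the marker
            free = [int(block[j]) for j in order if int(block[j]) not in taken]
            if free:
                idx = free[0]
        taken[idx] = gene
        causal_sites[gene] = id_col[idx]

    return MarkerMap(df, causal_sites)


def scaled_marker_map(
    n_markers: int,
    cm_per_kb: float = DEFAULT_CM_PER_KB,
    causal_overrides: Mapping[str, tuple[str, int]] | None = None,
    seed: int = 0,
) -> MarkerMap:
    """A scaled-down genome preserving the real data's marker density.

    Chromosome lengths are shrunk by ``n_markers / 36,756`` so the
    physical and genetic spacing between adjacent markers matches the full
    36,756-SNP map (~330 bp, ~0.13 cM at the default density).  This keeps
    a 10-SNP window at the same genetic span as in the real data, so the
    fixation signal at a causal site behaves the same at a fraction of the
    cost.  The trade-off is that same-chromosome loci sit much closer in
    cM than on the real genome; the backcross report resolves such loci by
    causal-site overlap rather than by run separation alone.
    """
    frac = n_markers / REFERENCE_SNP_COUNT
    lengths = {c: max(int(round(L * frac)), n_markers // 8 + 2)
               for c, L in CHROM_LENGTHS_BP.items()}
    return build_marker_map(n_markers, lengths, cm_per_kb, causal_overrides, seed)
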