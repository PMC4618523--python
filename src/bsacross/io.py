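"""Readers and writers for the package's plain-text formats.

All tabular formats are TSV with a header row; lines starting with ``#``
are metadata comments (seed, parameters) and are ignored on read.
Physical coordinates are 1-based inclusive throughout, except BED exports,
which follow the BED convention (0-based, half-open).
"""
from __future__ import annotations

import io as _io
import re
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd

from .cross import Haplotype, Segregant
from .mapping import LocusCall
from .markers import MarkerMap
from .pools import AlleleCountTable


def _write_tsv(df: pd.DataFrame, path, header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# -- marker map ----------------------------------------------------------

def write_marker_map(marker_map: MarkerMap, path,
                     header_lines: Sequence[str] = ()) -> None:
    _write_tsv(marker_map.to_frame(), path, header_lines)


def read_marker_map(path) -> MarkerMap:
    df = _read_tsv(path)
    df["causal_gene"] = df.get("causal_gene", pd.Series("", index=df.index)).fillna("")
    causal = {row.causal_gene: row.id for row in df.itertuples() if row.causal_gene}
    return MarkerMap(df.drop(columns=["causal_gene"]), causal)


# -- genotype matrix -----------------------------------------------------

def write_genotypes(pop: Sequence[Segregant], path,
                    header_lines: Sequence[str] = ()) -> None:
    """Rows = segregants, columns = marker ids plus side-car state columns."""
    if not pop:
        raise ValueError("cannot write an empty population")
    marker_map = pop[0].haplotype.map
    mat = np.stack([s.haplotype.origin_labels() for s in pop])
    df = pd.DataFrame(mat, columns=marker_map.marker_ids().to_numpy())
    df.insert(0, "segregant", [f"seg{i:05d}" for i in range(len(pop))])
    df["ira2_state"] = [s.haplotype.ira2_state for s in pop]
    df["sfl1_state"] = [s.haplotype.sfl1_state for s in pop]
    df["phenotype"] = [s.phenotype for s in pop]
    df["scheme"] = [s.scheme for s in pop]
    _write_tsv(df, path, header_lines)


def read_genotypes(path, marker_map: MarkerMap) -> list[Segregant]:
    df = _read_tsv(path)
    ids = marker_map.marker_ids().to_numpy()
    missing = [m for m in ids if m not in df.columns]
    if missing:
        raise ValueError(f"genotype table lacks {len(missing)} map markers "
                         f"(first: {missing[0]!r})")
    out = []
    mat = df[list(ids)].to_numpy()
    origins01 = (mat == "3S").astype(np.uint8)
    bad = ~np.isin(mat, ["BY", "3S"])
    if bad.any():
        raise ValueError("genotype cells must be BY or 3S")
    for i in range(len(df)):
        hap = Haplotype(origins01[i], marker_map,
                        ira2_state=df["ira2_state"].iloc[i],
                        sfl1_state=df["sfl1_state"].iloc[i])
        out.append(Segregant(hap, df["phenotype"].iloc[i], df["scheme"].iloc[i]))
    return out


# -- allele counts -------------------------------------------------------

def write_counts(table: AlleleCountTable, path,
                 header_lines: Sequence[str] = ()) -> None:
    _write_tsv(table.to_frame(), path, header_lines)


def read_counts(path, marker_map: MarkerMap) -> AlleleCountTable:
    df = _read_tsv(path)
    if not np.array_equal(df["id"].to_numpy(), marker_map.marker_ids().to_numpy()):
        raise ValueError("allele-count table does not match the marker map")
    mutant = {}
    if "mut_gene" in df.columns:
        for row in df.loc[df["mut_gene"].fillna("") != ""].itertuples():
            mutant[row.mut_gene] = (int(row.mut_count), int(row.mut_depth))
    return AlleleCountTable(marker_map, df["depth"].to_numpy(),
                            df["count_by"].to_numpy(), df["count_3s"].to_numpy(),
                            df["count_other"].to_numpy(), mutant)


# -- locus reports -------------------------------------------------------

def write_locus_report(report: pd.DataFrame, path,
                       header_lines: Sequence[str] = ()) -> None:
    _write_tsv(report, path, header_lines)


def write_bed(report: pd.DataFrame | Iterable[LocusCall], path,
              marker_map: MarkerMap | None = None) -> None:
    """BED6 export: 0-based half-open, name = fixed allele,
    score = round(1000 x mean frequency)."""
    if isinstance(report, pd.DataFrame):
        rows = report.to_dict("records")
    else:
        rows = [{"chrom": c.chrom, "start_bp": c.start_bp, "end_bp": c.end_bp,
                 "fixed_allele": c.fixed_allele, "mean_freq": c.mean_freq}
                for c in report]
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join([
                str(r["chrom"]), str(int(r["start_bp"]) - 1), str(int(r["end_bp"])),
                str(r["fixed_allele"]), str(int(round(1000 * float(r["mean_freq"])))),
                ".",
            ]) + "\n")


# -- mpileup -------------------------------------------------------------

_INDEL_RE = re.compile(r"^[+-](\d+)")


def _parse_pileup_bases(bases: str, ref: str) -> list[str]:
    """Resolve a samtools mpileup read-base string to called bases.

    Strips ``^`` (start-of-read + mapping quality char), ``$``
    (end-of-read), indel blocks (``+N``/``-N`` followed by N bases) and
    deleted-base placeholders (``*``); ``.``/``,`` resolve to the
    reference base.
    """
    out: list[str] = []
    i = 0
    n = len(bases)
    while i < n:
        ch = bases[i]
        if ch == "^":
            if i + 1 >= n:
                raise ValueError("dangling '^' in pileup base string")
            i += 2
            continue
        if ch == "$":
            i += 1
            continue
        if ch in "+-":
            m = _INDEL_RE.match(bases[i:])
            if not m:
                raise ValueError(f"malformed indel block at column {i}")
            k = int(m.group(1))
            i += m.end() + k
            continue
        if ch in "*#":
            i += 1
            continue
        if ch in ".,":
            out.append(ref.upper())
        elif ch.upper() in "ACGTN":
            out.append(ch.upper())
        else:
            raise ValueError(f"unexpected pileup character {ch!r}")
        i += 1
    return out


def read_mpileup_counts(stream: IO[str] | str,
                        snp_list: MarkerMap) -> AlleleCountTable:
    """Per-SNP BY/3S/other counts from samtools mpileup text.

    ``snp_list`` supplies 1-based positions and the two parental alleles.
    SNPs absent from the stream get zero-depth rows.  Malformed lines
    raise ``ValueError`` with the offending line number.
    """
    if isinstance(stream, str):
        stream = _io.StringIO(stream)
    wanted: dict[tuple[str, int], int] = {
        (snp_list.chrom[i], int(snp_list.pos_bp[i])): i
        for i in range(snp_list.n_markers)}
    n = snp_list.n_markers
    count_by = np.zeros(n, dtype=np.int64)
    count_3s = np.zeros(n, dtype=np.int64)
    count_other = np.zeros(n, dtype=np.int64)
    allele_by = snp_list.to_frame()["allele_by"].to_numpy()
    allele_3s = snp_list.to_frame()["allele_3s"].to_numpy()

    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 5:
            raise ValueError(f"mpileup line {lineno}: expected >= 5 columns")
        chrom, pos_s, ref = fields[0], fields[1], fields[2]
        try:
            pos = int(pos_s)
        except ValueError:
            raise ValueError(f"mpileup line {lineno}: bad position {pos_s!r}") from None
        idx = wanted.get((chrom, pos))
        if idx is None:
            continue
        try:
            called = _parse_pileup_bases(fields[4], ref)
        except ValueError as exc:
            raise ValueError(f"mpileup line {lineno}: {exc}") from None
        for base in called:
            if base == allele_by[idx].upper():
                count_by[idx] += 1
            elif base == allele_3s[idx].upper():
                count_3s[idx] += 1
            else:
                count_other[idx] += 1
    depth = count_by + count_3s + count_other
    return AlleleCountTable(snp_list, depth, count_by, count_3s, count_other)
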