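"""Readers and writers for the pipeline's on-disk formats.

Contacts use the HiC-Pro sparse convention: a ``.bed`` file of genome-wide
fixed-size bins (0-based half-open, with a 1-based bin index in column 4)
and a ``.matrix`` file of tab-separated upper-triangle triplets
(bin_i, bin_j, count) using those 1-based indices.  Everything else is
plain BED / TSV handled through pandas.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .scoring import BIN_SIZE

__all__ = [
    "make_bin_table",
    "write_hicpro",
    "read_hicpro",
    "write_peaks_bed",
    "read_peaks_bed",
    "write_tsv",
    "read_tsv",
]


def make_bin_table(chrom_sizes: dict, bin_size: int = BIN_SIZE) -> pd.DataFrame:
    """Genome-wide bin table with 1-based global ``bin_index``."""
    frames = []
    offset = 1
    for chrom, size in chrom_sizes.items():
        n = int(np.ceil(size / bin_size))
        starts = np.arange(n, dtype=np.int64) * bin_size
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "start": starts,
            "end": np.minimum(starts + bin_size, size),
            "bin_index": np.arange(offset, offset + n),
        }))
        offset += n
    return pd.concat(frames, ignore_index=True)


def write_hicpro(contacts: pd.DataFrame, chrom_sizes: dict, prefix,
                 bin_size: int = BIN_SIZE) -> None:
    """Write one sample's map as ``<prefix>.matrix`` + ``<prefix>_abs.bed``."""
    bins = make_bin_table(chrom_sizes, bin_size)
    first = bins.groupby("chrom", sort=False)["bin_index"].min()
    m = contacts.copy()
    m["bi"] = first.loc[m["chrom"]].to_numpy() + m["i"].to_numpy()
    m["bj"] = first.loc[m["chrom"]].to_numpy() + m["j"].to_numpy()
    m = m.sort_values(["bi", "bj"])
    prefix = str(prefix)
    bins.to_csv(prefix + "_abs.bed", sep="\t", header=False, index=False)
    m[["bi", "bj", "count"]].to_csv(prefix + ".matrix", sep="\t",
                                    header=False, index=False)


def read_hicpro(matrix_path, bed_path) -> pd.DataFrame:
    """Read a HiC-Pro pair back into the internal (chrom, i, j, count) form.

    Trans (inter-chromosome) triplets are dropped: scoring only consumes
    valid cis pairs.
    """
    bins = pd.read_csv(bed_path, sep="\t", header=None,
                       names=["chrom", "start", "end", "bin_index"])
    m = pd.read_csv(matrix_path, sep="\t", header=None, names=["bi", "bj", "count"])
    lk = bins.set_index("bin_index")
    first = bins.groupby("chrom", sort=False)["bin_index"].min()
    ci = lk.loc[m["bi"], "chrom"].to_numpy()
    cj = lk.loc[m["bj"], "chrom"].to_numpy()
    cis = ci == cj
    m, ci = m[cis], ci[cis]
    out = pd.DataFrame({
        "chrom": ci,
        "i": m["bi"].to_numpy() - first.loc[ci].to_numpy(),
        "j": m["bj"].to_numpy() - first.loc[ci].to_numpy(),
        "count": m["count"].to_numpy(),
    })
    lo = np.minimum(out["i"], out["j"])
    hi = np.maximum(out["i"], out["j"])
    out["i"], out["j"] = lo, hi
    return out


def write_peaks_bed(peaks: pd.DataFrame, path) -> None:
    """BED6+1: chrom, start, end, name, score(0), strand(.), summit."""
    df = peaks[["chrom", "start", "end", "peak_id"]].copy()
    df["score"] = 0
    df["strand"] = "."
    df["summit"] = peaks["summit"]
    df.to_csv(path, sep="\t", header=False, index=False)


def read_peaks_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "peak_id",
                            "score", "strand", "summit"])
    return df[["peak_id", "chrom", "start", "end", "summit"]]


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kw)
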