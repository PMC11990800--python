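"""Readers and writers for the package's plain-text interchange formats.

All tabular formats are TSV with a comment header naming the producing
version; coordinates in exported CN tables are BED-style 0-based half-open bp
intervals.  Trees are Newick with branch lengths in simulation time units.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .genome import GenomeSpec, build_genome
from .genotype import CloneGenotype, Mutation
from .selection import DriverGene

__all__ = [
    "write_genome_tsv", "read_genome_tsv",
    "write_drivers_tsv", "read_drivers_tsv",
    "write_cn_profiles", "read_cn_profiles",
    "write_arm_frequencies", "read_arm_frequencies",
    "write_clone_trajectories",
    "write_newick", "read_newick",
    "write_posterior_tsv", "read_posterior_tsv",
    "config_hash",
]


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serialisable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _header(extra: str = "") -> str:
    tail = f" {extra}" if extra else ""
    return f"# karyosim v{__version__}{tail}\n"


def _read_tsv(path, columns):
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


# -- genome ---------------------------------------------------------------

def write_genome_tsv(genome: GenomeSpec, path) -> None:
    with open(path, "w") as fh:
        fh.write(_header())
        fh.write("chrom\tlength_bp\tcentromere_bp\n")
        for name, ln, cen in zip(
            genome.chrom_names, genome.chrom_lengths,
            genome.centromere_bin * genome.bin_size,
        ):
            fh.write(f"{name}\t{ln}\t{int(cen)}\n")


def read_genome_tsv(path, bin_size: int) -> GenomeSpec:
    df = _read_tsv(path, ["chrom", "length_bp", "centromere_bp"])
    return build_genome(
        df["length_bp"].tolist(),
        df["centromere_bp"].tolist(),
        bin_size,
        chrom_names=df["chrom"].tolist(),
    )


# -- driver library -------------------------------------------------------

def write_drivers_tsv(drivers, genome: GenomeSpec, path) -> None:
    with open(path, "w") as fh:
        fh.write(_header())
        fh.write("gene\trole\tchrom\tbin\tlambda\n")
        for d in drivers:
            fh.write(
                f"{d.name}\t{d.role}\t{genome.chrom_names[d.chrom]}\t{d.bin}\t{d.rate}\n"
            )


def read_drivers_tsv(path, genome: GenomeSpec):
    df = _read_tsv(path, ["gene", "role", "chrom", "bin", "lambda"])
    name_to_idx = {n: i for i, n in enumerate(genome.chrom_names)}
    out = []
    for _, row in df.iterrows():
        chrom = name_to_idx[str(row["chrom"])]
        out.append(
            DriverGene(str(row["gene"]), str(row["role"]), float(row["lambda"]),
                       chrom, int(row["bin"]))
        )
    return out


# -- per-cell CN profiles -------------------------------------------------

def write_cn_profiles(profiles: dict, genome: GenomeSpec, path) -> None:
    """Write ``{cell_id: CloneGenotype}`` as a BED-style homolog CN table."""
    with open(path, "w") as fh:
        fh.write(_header())
        fh.write("cell_id\tchrom\tstart\tend\thomolog\tcopy_number\n")
        for cell, g in profiles.items():
            for i, arr in enumerate(g.cn):
                name = genome.chrom_names[i]
                length = genome.chrom_lengths[i]
                for j in range(arr.shape[0]):
                    row = arr[j]
                    # merge runs of equal CN into intervals
                    b = 0
                    while b < len(row):
                        e = b
                        while e + 1 < len(row) and row[e + 1] == row[b]:
                            e += 1
                        start = b * genome.bin_size
                        end = min((e + 1) * genome.bin_size, length)
                        fh.write(f"{cell}\t{name}\t{start}\t{end}\t{j}\t{int(row[b])}\n")
                        b = e + 1


def read_cn_profiles(path, genome: GenomeSpec) -> dict:
    """Read a CN table back into ``{cell_id: CloneGenotype}`` (no mutations)."""
    df = _read_tsv(path, ["cell_id", "chrom", "start", "end", "homolog", "copy_number"])
    name_to_idx = {n: i for i, n in enumerate(genome.chrom_names)}
    out = {}
    for cell, sub in df.groupby("cell_id", sort=False):
        cn = []
        for i in range(genome.n_chroms):
            rows = sub[sub["chrom"].astype(str) == genome.chrom_names[i]]
            n_hom = int(rows["homolog"].max()) + 1 if len(rows) else 0
            arr = np.zeros((n_hom, int(genome.bins_per_chrom[i])), dtype=np.int32)
            for _, r in rows.iterrows():
                b0 = int(r["start"]) // genome.bin_size
                b1 = -(-int(r["end"]) // genome.bin_size)
                arr[int(r["homolog"]), b0:b1] = int(r["copy_number"])
            cn.append(arr)
        out[cell] = CloneGenotype(cn)
    return out


# -- cohort summaries -----------------------------------------------------

def write_arm_frequencies(freq_df: pd.DataFrame, path, meta: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(_header(meta))
        freq_df.to_csv(fh, sep="\t", index=False)


def read_arm_frequencies(path) -> pd.DataFrame:
    return _read_tsv(path, ["arm", "fr_gain", "fr_loss"])


def write_clone_trajectories(history, path) -> None:
    with open(path, "w") as fh:
        fh.write(_header())
        fh.write("time\tclone_id\tparent_id\tcell_count\tdivisions\tfitness\n")
        for c in history.clones:
            for k, n in enumerate(c.counts):
                g = c.first_index + k
                t = history.times[g] if g < len(history.times) else None
                if t is None:
                    continue
                parent = c.parent if c.parent is not None else -1
                fh.write(
                    f"{t:.6g}\t{c.id}\t{parent}\t{n}\t{c.divisions[k]}\t{c.fitness:.6g}\n"
                )


# -- trees ----------------------------------------------------------------

def write_newick(tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def read_newick(path):
    """Parse a Newick file with dendropy; returns a ``dendropy.Tree``."""
    import dendropy

    return dendropy.Tree.get(path=str(path), schema="newick")


# -- posteriors -----------------------------------------------------------

def write_posterior_tsv(posterior, path) -> None:
    """Write posterior draws/weights: columns parameter, draw, weight."""
    with open(path, "w") as fh:
        fh.write(_header())
        fh.write("parameter\tdraw\tweight\n")
        for name, (draws, weights) in posterior.draws.items():
            for d, w in zip(draws, weights):
                fh.write(f"{name}\t{d:.8g}\t{w:.8g}\n")


def read_posterior_tsv(path) -> pd.DataFrame:
    return _read_tsv(path, ["parameter", "draw", "weight"])
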