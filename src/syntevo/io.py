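"""File formats, fixtures and run configuration.

All tabular outputs are tidy TSV with headers; anything interval-shaped
is written as BED (0-based, half-open) so standard genome browsers can
load EBR/msHSB calls directly.  Readers convert 1-based inputs at this
boundary when asked and reject malformed rows with line numbers.

The packaged chicken-orthology table of the reconstructed mammalian
ancestor chromosomes (MAM <-> GGA, with complete/partial calls) was
transcribed once from the printed karyotype table and is frozen with a
checksum.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .core import BlockGenome, DatedTree, Interval, ValidationError
from .features import EBR, MsHSB

_TABLE1_SHA256 = "aa8626901b448975df3122bb312b0e363e2f8782fbff44473500bd540bcaea3f"

# ---------------------------------------------------------------------------
# Block tables
# ---------------------------------------------------------------------------

BLOCK_COLUMNS = ["genome", "chromosome", "order", "block", "sign", "length"]


def write_block_table(genomes: Iterable[BlockGenome], path: str | Path) -> None:
    rows = []
    for g in genomes:
        for chrom in sorted(g.chromosomes):
            for i, b in enumerate(g.chromosomes[chrom]):
                rows.append(
                    {
                        "genome": g.name,
                        "chromosome": chrom,
                        "order": i,
                        "block": abs(b),
                        "sign": 1 if b > 0 else -1,
                        "length": g.block_lengths[abs(b)],
                    }
                )
    pd.DataFrame(rows, columns=BLOCK_COLUMNS).to_csv(path, sep="\t", index=False)


def read_block_table(path: str | Path) -> dict[str, BlockGenome]:
    """Read one or more genomes from a block-table TSV.

    Rejects duplicate blocks, non-positive lengths, and unsorted order
    indices, naming the offending line.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(BLOCK_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    out: dict[str, BlockGenome] = {}
    for genome, gdf in df.groupby("genome", sort=False):
        chroms: dict[str, list[int]] = {}
        lengths: dict[int, int] = {}
        seen: set[int] = set()
        for chrom, cdf in gdf.groupby("chromosome", sort=False):
            expected = 0
            for row in cdf.itertuples():
                line = row.Index + 2  # header + 0-base
                if row.order != expected:
                    raise ValidationError(
                        f"{path}:{line}: unsorted order index for {genome}/{chrom}"
                    )
                expected += 1
                if row.block in seen:
                    raise ValidationError(
                        f"{path}:{line}: duplicate block {row.block} in genome {genome}"
                    )
                seen.add(row.block)
                if row.length <= 0:
                    raise ValidationError(
                        f"{path}:{line}: non-positive length for block {row.block}"
                    )
                chroms.setdefault(str(chrom), []).append(int(row.block * row.sign))
                lengths[int(row.block)] = int(row.length)
        out[str(genome)] = BlockGenome(str(genome), chroms, lengths)
    return out


# ---------------------------------------------------------------------------
# Orthology tables
# ---------------------------------------------------------------------------

ORTHOLOGY_COLUMNS = [
    "block",
    "ref_chrom",
    "ref_start",
    "ref_end",
    "tgt_chrom",
    "tgt_start",
    "tgt_end",
    "orientation",
]


def write_orthology_table(table: pd.DataFrame, path: str | Path) -> None:
    table[ORTHOLOGY_COLUMNS].to_csv(path, sep="\t", index=False)


def read_orthology_table(path: str | Path, one_based: bool = False) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(ORTHOLOGY_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    if one_based:
        df = df.assign(
            ref_start=df["ref_start"] - 1, tgt_start=df["tgt_start"] - 1
        )
    bad = df[(df["ref_start"] < 0) | (df["ref_start"] >= df["ref_end"])]
    if len(bad):
        raise ValidationError(
            f"{path}:{bad.index[0] + 2}: invalid reference interval"
        )
    if not set(df["orientation"]) <= {1, -1}:
        raise ValidationError(f"{path}: orientation must be +1/-1")
    return df


# ---------------------------------------------------------------------------
# BED tracks
# ---------------------------------------------------------------------------


def write_bed(
    intervals: Iterable[Interval | tuple[Interval, str]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for item in intervals:
            iv, name = item if isinstance(item, tuple) else (item, ".")
            strand = {1: "+", -1: "-", 0: "."}[iv.strand]
            fh.write(f"{iv.chromosome}\t{iv.start}\t{iv.end}\t{name}\t0\t{strand}\n")


def read_bed(path: str | Path, track: str | None = None) -> list[Interval]:
    """Read a BED3+ file into intervals (0-based, half-open)."""
    out = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            raw = raw.strip()
            if not raw or raw.startswith(("#", "track", "browser")):
                continue
            parts = raw.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}:{ln}: fewer than 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValidationError(f"{path}:{ln}: non-numeric coordinates") from exc
            if start >= end or start < 0:
                raise ValidationError(f"{path}:{ln}: start >= end")
            strand = 0
            if len(parts) >= 6:
                strand = {"+": 1, "-": -1}.get(parts[5], 0)
            out.append(Interval(parts[0], start, end, strand))
    return out


def read_bed_named(path: str | Path) -> list[tuple[Interval, str]]:
    out = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            raw = raw.strip()
            if not raw or raw.startswith(("#", "track", "browser")):
                continue
            parts = raw.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}:{ln}: fewer than 3 BED columns")
            start, end = int(parts[1]), int(parts[2])
            if start >= end:
                raise ValidationError(f"{path}:{ln}: start >= end")
            name = parts[3] if len(parts) > 3 else "."
            out.append((Interval(parts[0], start, end), name))
    return out


def write_ebr_bed(ebrs: Sequence[EBR], path: str | Path) -> None:
    """EBR calls as BED; the name field carries branch and flags."""
    items = []
    for e in ebrs:
        flags = []
        if e.reuse:
            flags.append("reuse=" + ",".join(e.reuse_lineages))
        if e.placeholder:
            flags.append("placeholder")
        if e.centromere_associated:
            flags.append("centromeric")
        name = e.branch + ("|" + "|".join(flags) if flags else "")
        items.append((e.interval, name))
    write_bed(items, path)


def write_mshsb_bed(mshsbs: Sequence[MsHSB], path: str | Path) -> None:
    write_bed([(m.interval, f"msHSB_{i+1}") for i, m in enumerate(mshsbs)], path)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def read_tree(path: str | Path) -> DatedTree:
    return DatedTree.from_newick(Path(path).read_text())


def write_tree(tree: DatedTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


# ---------------------------------------------------------------------------
# Packaged karyotype-orthology fixture
# ---------------------------------------------------------------------------


def load_mam_gga_table(verify: bool = True) -> pd.DataFrame:
    """The transcribed MAM <-> chicken (GGA) orthology table.

    One row per (ancestral chromosome, chicken chromosome segment);
    ``complete`` marks chicken chromosomes wholly orthologous to that
    single ancestral chromosome.
    """
    ref = resources.files("syntevo.data") / "mam_gga_orthology.tsv"
    raw = ref.read_bytes()
    if verify and hashlib.sha256(raw).hexdigest() != _TABLE1_SHA256:
        raise ValidationError("packaged orthology fixture failed its checksum")
    df = pd.read_csv(ref, sep="\t", dtype={"mam": str, "gga": str})
    return df


def mam_gga_correspondence(table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Fixture rows as a correspondence map for orthology classification.

    Printed complete/partial calls become coverage fractions: a complete
    chicken chromosome counts as fully covered (1.0), a partial segment
    as fractional (0.5, below any completeness tolerance).  The table
    lists each ancestral chromosome's full composition, so its own side
    is complete by construction.
    """
    df = load_mam_gga_table() if table is None else table
    rows = []
    counts = df.groupby("mam")["gga"].transform("count")
    for (_, row), n in zip(df.iterrows(), counts):
        rows.append(
            {
                "chrom_a": f"MAM{row['mam']}",
                "chrom_b": f"GGA{row['gga']}",
                "frac_a": 1.0 / n,
                "frac_b": 1.0 if row["complete"] == 1 else 0.5,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Run configuration and manifest
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Parameters of a pipeline run; thresholds anchored at 300 kbp."""

    seed: int = 0
    resolution: int = 300_000  # SF resolution, shared with min msHSB length
    window_widths: tuple[int, int] = (10_000, 100_000)
    min_mshsb_length: int = 300_000
    reuse_size_gate: int = 300_000
    min_ebr_width: int = 300_000
    alpha: float = 0.05
    correction: str = "bonferroni"  # pairwise tests; rates use BH FDR
    # simulation
    tree_newick: str = (
        "((((A:0.5,B:0.5)AB:0.5,(C:0.5,D:0.5)CD:0.5)ABCD:0.5,E:1.5)ABCDE:0.5,"
        "F:2.0)root;"
    )
    n_blocks: int = 100
    n_chromosomes: int = 5
    mean_block_length: int = 100_000
    block_length_sigma: float = 0.4
    min_block_length: int = 50_000
    rate: float = 2.0
    mix: tuple[float, float, float] = (0.8, 0.1, 0.1)
    reference: str = "root"

    def __post_init__(self) -> None:
        for name in ("resolution", "min_mshsb_length", "reuse_size_gate", "min_ebr_width"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "window_widths" in data:
            data["window_widths"] = tuple(data["window_widths"])
        if "mix" in data:
            data["mix"] = tuple(data["mix"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["window_widths"] = list(self.window_widths)
        d["mix"] = list(self.mix)
        return d


def write_manifest(
    out_dir: str | Path, config: RunConfig, inputs: Mapping[str, str | Path] = {}
) -> Path:
    """Record config, versions, seed and input checksums for a run."""
    from . import __version__

    manifest = {
        "package": "syntevo",
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config": config.to_dict(),
        "input_checksums": {
            name: hashlib.sha256(Path(p).read_bytes()).hexdigest()
            for name, p in sorted(inputs.items())
        },
    }
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
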