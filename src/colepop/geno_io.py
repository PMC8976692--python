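"""Genotype, metadata, window-statistic and tree I/O.

The central container is :class:`GenotypeMatrix`: accessions × biallelic SNP
loci, coded as the diploid dosage of the alternate allele (0, 1, 2) with
``MISSING = -1`` for no-calls.  Coordinates are 1-based inclusive throughout,
following VCF convention.  Which allele is "alternate" is taken from the file
and never re-polarised; every statistic in this package is invariant to an
allele-label swap.

Trees are :class:`dendropy.Tree` objects; the thin wrappers here add the
validation (unique tip labels, balanced parentheses) and a fixed float format
so Newick round-trips preserve branch lengths to 10 significant digits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

from .errors import EmptyInputError, ParseError, ValidationError

logger = logging.getLogger(__name__)

#: Sentinel dosage code for a missing diploid call.
MISSING: int = -1

#: Token used for an unknown subgroup / region in metadata (not missing data:
#: parsimony treats it as "any state").
UNKNOWN: str = "UNKNOWN"

_VALID_SOURCE_CLASSES = frozenset({"genebank", "hybrid", "other"})

METADATA_COLUMNS = ["accession_id", "morphotype", "subgroup", "source_class", "region"]


@dataclass
class GenotypeMatrix:
    """Accessions × loci diploid dosage matrix.

    Parameters
    ----------
    accession_ids
        Ordered, unique accession identifiers (rows).
    chrom
        Chromosome label per locus (columns).
    pos
        1-based bp position per locus; unique within a chromosome and sorted
        by (chromosome, position).
    calls
        ``(n_accessions, n_loci)`` int8 array in {0, 1, 2, MISSING}.
    """

    accession_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.accession_ids = [str(a) for a in self.accession_ids]
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if len(self.accession_ids) < 2:
            raise ValidationError("a genotype matrix needs at least 2 accessions")
        if len(set(self.accession_ids)) != len(self.accession_ids):
            raise ValidationError("duplicate accession ids")
        if self.pos.size < 1:
            raise ValidationError("a genotype matrix needs at least 1 locus")
        if self.calls.shape != (len(self.accession_ids), self.pos.size):
            raise ValidationError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.accession_ids)} accessions x {self.pos.size} loci"
            )
        ok = np.isin(self.calls, (0, 1, 2, MISSING))
        if not ok.all():
            bad = self.calls[~ok].ravel()[0]
            raise ValidationError(f"invalid dosage code {bad}; allowed are 0,1,2,{MISSING}")
        order = np.lexsort((self.pos, _chrom_sort_key(self.chrom)))
        if not np.array_equal(order, np.arange(self.pos.size)):
            self.chrom = self.chrom[order]
            self.pos = self.pos[order]
            self.calls = self.calls[:, order]
        for c in np.unique(self.chrom.astype(str)):
            p = self.pos[self.chrom == c]
            if np.unique(p).size != p.size:
                raise ValidationError(f"duplicate position on chromosome {c}")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    @property
    def n_loci(self) -> int:
        return int(self.pos.size)

    @property
    def loci(self) -> list[tuple[str, int]]:
        return [(str(c), int(p)) for c, p in zip(self.chrom, self.pos)]

    def locus_ids(self) -> list[str]:
        return [f"{c}:{p}" for c, p in zip(self.chrom, self.pos)]

    def accession_index(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.accession_ids)}
        try:
            return np.array([lookup[a] for a in ids], dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - message path
            raise ValidationError(f"unknown accession id {exc.args[0]!r}") from None

    def subset(self, ids: Sequence[str]) -> "GenotypeMatrix":
        idx = self.accession_index(ids)
        return GenotypeMatrix(list(ids), self.chrom.copy(), self.pos.copy(), self.calls[idx])

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.accession_ids == other.accession_ids
            and np.array_equal(self.chrom.astype(str), other.chrom.astype(str))
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.calls, other.calls)
        )


def _chrom_sort_key(chrom: np.ndarray) -> np.ndarray:
    labels = sorted(set(chrom.astype(str)))
    rank = {c: i for i, c in enumerate(labels)}
    return np.array([rank[str(c)] for c in chrom], dtype=np.int64)


@dataclass(frozen=True)
class WindowStat:
    """One genomic window's statistic (π per bp or F_ST)."""

    chromosome: str
    start: int  # 1-based inclusive
    end: int  # inclusive
    value: float
    n_sites: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"window start {self.start} > end {self.end}")
        if self.n_sites < 0:
            raise ValidationError("n_sites must be >= 0")


# --------------------------------------------------------------------------- #
# VCF
# --------------------------------------------------------------------------- #


def read_vcf(path: str | Path, *, strict_biallelic: bool = False) -> GenotypeMatrix:
    """Read biallelic SNP genotypes from a VCF 4.x file.

    GT fields are mapped to alternate-allele dosage (0/0→0, 0/1→1, 1/1→2,
    ./.→MISSING).  Multiallelic or non-SNP records are skipped with a warning
    (or rejected when ``strict_biallelic``).
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:
        raise ParseError(f"cannot open VCF {path!r}: {exc}") from exc
    samples = list(vcf.samples)
    if len(samples) < 2:
        raise ValidationError("VCF must contain at least 2 samples")
    chroms: list[str] = []
    positions: list[int] = []
    columns: list[np.ndarray] = []
    n_skipped = 0
    try:
        for variant in vcf:
            if len(variant.ALT) != 1 or not variant.is_snp:
                if strict_biallelic:
                    raise ParseError(
                        f"non-biallelic-SNP record at {variant.CHROM}:{variant.POS}"
                    )
                n_skipped += 1
                continue
            # gt_types: 0=hom-ref, 1=het, 3=hom-alt, 2=unknown
            gt = np.asarray(variant.gt_types)
            col = np.full(gt.shape, MISSING, dtype=np.int8)
            col[gt == 0] = 0
            col[gt == 1] = 1
            col[gt == 3] = 2
            chroms.append(variant.CHROM)
            positions.append(variant.POS)
            columns.append(col)
    except ParseError:
        raise
    except Exception as exc:
        raise ParseError(
            f"malformed VCF {path!r} near record {len(chroms) + n_skipped + 1}: {exc}"
        ) from exc
    if n_skipped:
        logger.warning("skipped %d non-biallelic-SNP records in %s", n_skipped, path)
    if not columns:
        raise EmptyInputError(f"no biallelic SNP records in {path!r}")
    calls = np.stack(columns, axis=1)
    return GenotypeMatrix(samples, np.array(chroms, dtype=object), np.array(positions), calls)


def write_vcf(gm: GenotypeMatrix, path: str | Path, *, ref: str = "A", alt: str = "T") -> None:
    """Write a minimal uncompressed VCF 4.2 with GT-only genotypes.

    REF/ALT nucleotides are placeholders: dosage coding carries no nucleotide
    identity, and no downstream statistic depends on it.
    """
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in dict.fromkeys(gm.chrom.astype(str)):
            length = int(gm.pos[gm.chrom == c].max())
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.accession_ids) + "\n")
        for j in range(gm.n_loci):
            gts = "\t".join(gt_map[int(g)] for g in gm.calls[:, j])
            fh.write(f"{gm.chrom[j]}\t{gm.pos[j]}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")


# --------------------------------------------------------------------------- #
# genotype TSV dialect: header "accession_id  chrom:pos ...", cells 0/1/2/NA
# --------------------------------------------------------------------------- #


def read_genotype_tsv(path: str | Path) -> GenotypeMatrix:
    """Read the plain accession×locus TSV dialect (cells in {0,1,2,NA})."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected accession_id column plus >=1 locus column")
    locus_cols = list(df.columns[1:])
    chroms, positions = [], []
    for col in locus_cols:
        chrom, _, p = col.rpartition(":")
        if not chrom or not p.isdigit():
            raise ParseError(f"{path}: locus header {col!r} is not 'chrom:pos'")
        chroms.append(chrom)
        positions.append(int(p))
    cells = df[locus_cols].to_numpy()
    calls = np.full(cells.shape, MISSING, dtype=np.int8)
    valid = {"0": 0, "1": 1, "2": 2, "NA": MISSING}
    for token, code in valid.items():
        calls[cells == token] = code
    bad = ~np.isin(cells, list(valid))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValidationError(
            f"{path}: invalid genotype cell {cells[r, c]!r} "
            f"(accession {df.iloc[r, 0]!r}, locus {locus_cols[c]!r})"
        )
    return GenotypeMatrix(list(df.iloc[:, 0]), np.array(chroms, dtype=object),
                          np.array(positions), calls)


def write_genotype_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    cells = gm.calls.astype(object)
    cells[gm.calls == MISSING] = "NA"
    df = pd.DataFrame(cells, columns=gm.locus_ids())
    df.insert(0, "accession_id", gm.accession_ids)
    df.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------- #
# accession metadata
# --------------------------------------------------------------------------- #


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the accession metadata TSV.

    Required columns: accession_id, morphotype, subgroup, source_class,
    region.  Empty subgroup/region cells become the explicit UNKNOWN token.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ParseError(f"{path}: metadata is missing columns {missing_cols}")
    df = df[METADATA_COLUMNS].copy()
    for col in ("subgroup", "region"):
        df.loc[df[col].str.strip() == "", col] = UNKNOWN
    if df["accession_id"].duplicated().any():
        dup = df.loc[df["accession_id"].duplicated(), "accession_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate accession_id {dup!r}")
    bad = ~df["source_class"].isin(_VALID_SOURCE_CLASSES)
    if bad.any():
        raise ValidationError(
            f"{path}: invalid source_class {df.loc[bad, 'source_class'].iloc[0]!r} "
            f"(allowed: {sorted(_VALID_SOURCE_CLASSES)})"
        )
    return df


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta[METADATA_COLUMNS].to_csv(path, sep="\t", index=False)


def check_paired(gm: GenotypeMatrix, meta: pd.DataFrame) -> None:
    """Assert the metadata covers exactly the matrix's accessions."""
    a, b = set(gm.accession_ids), set(meta["accession_id"])
    if a != b:
        raise ValidationError(
            f"metadata/matrix accession mismatch: {sorted(a ^ b)[:5]} ..."
        )


# --------------------------------------------------------------------------- #
# window statistics (BED-like TSV)
# --------------------------------------------------------------------------- #


def write_window_stats(stats: Sequence[WindowStat], path: str | Path) -> None:
    df = pd.DataFrame(
        [(w.chromosome, w.start, w.end, w.value, w.n_sites) for w in stats],
        columns=["chrom", "start", "end", "value", "n_sites"],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_window_stats(path: str | Path) -> list[WindowStat]:
    df = pd.read_csv(path, sep="\t")
    return [
        WindowStat(str(r.chrom), int(r.start), int(r.end), float(r.value), int(r.n_sites))
        for r in df.itertuples()
    ]


# --------------------------------------------------------------------------- #
# Newick trees (dendropy-backed)
# --------------------------------------------------------------------------- #


def read_newick(source: str | Path, *, rooted: bool = True) -> dendropy.Tree:
    """Parse a Newick tree from a path or a literal Newick string.

    Internal-node labels are kept as support/labels on the nodes.  Duplicate
    tip labels and malformed Newick raise.
    """
    text = str(source)
    if not text.lstrip().startswith("(") and Path(text).exists():
        text = Path(text).read_text()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                rooting="force-rooted" if rooted else "default-unrooted",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:
            if "Multiple occurrences" in str(exc):
                raise ValidationError(f"duplicate tip label: {exc}") from exc
            raise ParseError(f"malformed Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]
    if len(set(labels)) != len(labels):
        dup = next(l for l in labels if labels.count(l) > 1)
        raise ValidationError(f"duplicate tip label {dup!r}")
    if len(labels) < 2:
        raise ParseError("tree has fewer than 2 labelled tips")
    return tree


def tree_to_newick(tree: dendropy.Tree) -> str:
    """Serialise with 10-significant-digit branch lengths, supports as labels."""
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".10g",
        suppress_annotations=True,
        unquoted_underscores=True,
    )
    return s.strip()


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(tree_to_newick(tree) + "\n")
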