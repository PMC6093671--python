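"""Genotype matrices and VCF-backed I/O.

The central container is :class:`GenotypeMatrix`: a samples x loci table of
alt-allele dosage calls for bi-allelic SNPs.  Dosage coding counts ALT
alleles — 0 (hom-ref), 1 (het), 2 (hom-alt) — with :data:`MISSING` (-1) for
uncalled genotypes.  Triploid individuals genotyped through a diploid caller
are represented by the same three dosage states; nothing in the container is
ploidy-aware.

Coordinates are 1-based as in VCF.  Loci are kept sorted by (chrom, pos);
chromosome order is lexicographic on the chromosome name.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Sentinel for an uncalled genotype in the dosage table.
MISSING: int = -1

_NUCLEOTIDES = frozenset("ACGT")


class VcfFormatError(ValueError):
    """Raised when a VCF cannot be parsed as bi-allelic SNP genotype data."""


class SampleIdentityError(ValueError):
    """Raised when sample identifiers collide or are otherwise unusable."""


@dataclass(frozen=True)
class Locus:
    """A bi-allelic SNP.

    Parameters
    ----------
    chrom : str
        Chromosome (contig) name.
    pos : int
        1-based base-pair position.
    ref, alt : str
        Single-nucleotide reference and alternate alleles; must differ.
    mean_depth : float
        Mean per-genotype read depth across non-missing calls at this locus
        (NaN when no depth information is available).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    mean_depth: float = float("nan")

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"locus position must be >= 1, got {self.pos}")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(
                f"only single-nucleotide alleles are supported "
                f"(got {self.ref!r}/{self.alt!r} at {self.chrom}:{self.pos})"
            )
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles identical at {self.chrom}:{self.pos}")


@dataclass
class SampleMeta:
    """Free-form annotation attached to one accession."""

    sample_id: str
    species_label: str = ""
    origin_label: str = ""
    harvest_label: str = ""
    notes: str = ""


@dataclass
class GenotypeMatrix:
    """Samples x loci table of alt-allele dosage calls.

    Attributes
    ----------
    sample_ids : list of str
        Ordered, unique accession identifiers (rows of ``calls``).
    loci : list of Locus
        Ordered loci (columns of ``calls``), sorted by (chrom, pos) with no
        duplicate coordinate.
    calls : ndarray of int8, shape (n_samples, n_loci)
        Dosage calls in {0, 1, 2, MISSING}.
    depth : ndarray of int32 or None
        Per-genotype read depths; optional.
    """

    sample_ids: list[str]
    loci: list[Locus]
    calls: np.ndarray
    depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.loci)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.loci)} loci"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = pd.Series(self.sample_ids).value_counts()
            raise SampleIdentityError(
                f"duplicate sample ids: {sorted(dupes[dupes > 1].index)}"
            )
        bad = ~np.isin(self.calls, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("calls must be in {0, 1, 2, MISSING}")
        keys = [(l.chrom, l.pos) for l in self.loci]
        if any(b <= a for a, b in zip(keys, keys[1:])):
            raise ValueError("loci must be strictly sorted by (chrom, pos)")
        if self.depth is not None:
            self.depth = np.asarray(self.depth, dtype=np.int32)
            if self.depth.shape != self.calls.shape:
                raise ValueError("depth table shape must match calls")
            if (self.depth < 0).any():
                raise ValueError("depths must be non-negative")

    # -- basic geometry -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def missing_mask(self) -> np.ndarray:
        """Boolean samples x loci mask, True where the call is MISSING."""
        return self.calls == MISSING

    def locus_frame(self) -> pd.DataFrame:
        """Locus metadata as a DataFrame (chrom, pos, ref, alt, mean_depth)."""
        return pd.DataFrame(
            [dataclasses.asdict(l) for l in self.loci],
            columns=["chrom", "pos", "ref", "alt", "mean_depth"],
        )

    # -- subsetting -----------------------------------------------------

    def take_loci(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the loci at ``index`` (order preserved)."""
        index = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            loci=[self.loci[i] for i in index],
            calls=self.calls[:, index].copy(),
            depth=None if self.depth is None else self.depth[:, index].copy(),
        )

    def take_samples(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the samples at ``index`` (order preserved)."""
        index = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in index],
            loci=list(self.loci),
            calls=self.calls[index, :].copy(),
            depth=None if self.depth is None else self.depth[index, :].copy(),
        )

    def subset_samples(self, ids: Iterable[str]) -> "GenotypeMatrix":
        """New matrix restricted to the given sample ids (matrix order kept)."""
        wanted = set(ids)
        unknown = wanted - set(self.sample_ids)
        if unknown:
            raise SampleIdentityError(f"unknown sample ids: {sorted(unknown)}")
        idx = [i for i, s in enumerate(self.sample_ids) if s in wanted]
        return self.take_samples(idx)


# ----------------------------------------------------------------------
# frequencies


def allele_frequencies(g: GenotypeMatrix) -> np.ndarray:
    """Plug-in alt-allele frequency per locus.

    freq = (sum of dosages) / (2 x number of non-missing calls); MISSING
    calls contribute to neither numerator nor denominator.  A locus with no
    non-missing call gets NaN (undefined, never silently 0).
    """
    obs = (g.calls != MISSING).sum(axis=0)
    alt = np.where(g.calls == MISSING, 0, g.calls).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(obs > 0, alt / (2.0 * np.maximum(obs, 1)), np.nan)
    n_undef = int((obs == 0).sum())
    if n_undef:
        log.warning("%d loci have no non-missing calls; frequency undefined", n_undef)
    return freq


def minor_allele_frequencies(g: GenotypeMatrix) -> np.ndarray:
    """Folded frequency min(p, 1-p) per locus; NaN where undefined.

    Folding happens in allele-count space (min(alt, ref) / total) so that a
    locus at frequency f and one at 1-f get bit-identical MAF values.
    """
    obs = (g.calls != MISSING).sum(axis=0)
    alt = np.where(g.calls == MISSING, 0, g.calls).sum(axis=0)
    total = 2 * obs
    minor = np.minimum(alt, total - alt)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(obs > 0, minor / np.maximum(total, 1), np.nan)


# ----------------------------------------------------------------------
# VCF I/O

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def read_vcf(path: str | Path, min_genotype_depth: int = 8) -> GenotypeMatrix:
    """Read a multi-sample VCF into a :class:`GenotypeMatrix`.

    Only bi-allelic SNP records are kept.  Genotypes whose per-genotype
    depth (FORMAT/DP) is below ``min_genotype_depth`` are set to MISSING;
    when the file carries no DP field the depth rule is skipped with a
    warning.  Both phased (``|``) and unphased (``/``) genotypes are
    accepted; half-calls such as ``./1`` are treated as MISSING.

    Raises
    ------
    VcfFormatError
        If the file cannot be parsed as VCF.
    SampleIdentityError
        If sample ids are duplicated.
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path, gts012=False)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise VcfFormatError(f"cannot open {path!r} as VCF: {exc}") from exc

    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise SampleIdentityError(f"duplicate sample ids in {path!r}")
    n = len(samples)

    loci: list[Locus] = []
    call_cols: list[np.ndarray] = []
    depth_cols: list[np.ndarray] = []
    have_depth = True
    n_nonsnp = 0

    try:
        for v in vcf:
            if len(v.ALT) != 1:
                n_nonsnp += 1
                continue
            ref, alt = v.REF.upper(), v.ALT[0].upper()
            if len(ref) != 1 or len(alt) != 1 or ref not in _NUCLEOTIDES or alt not in _NUCLEOTIDES:
                n_nonsnp += 1
                continue
            dosage = np.full(n, MISSING, dtype=np.int8)
            for i, gt in enumerate(v.genotypes):
                a, b = gt[0], gt[1]
                if a < 0 or b < 0:  # includes half calls like ./1
                    continue
                dosage[i] = (a > 0) + (b > 0)
            dp = v.format("DP")
            if dp is None:
                have_depth = False
                col_depth = None
            else:
                col_depth = np.asarray(dp, dtype=np.int64).reshape(n)
                col_depth = np.where(col_depth < 0, 0, col_depth)
                low = (col_depth < min_genotype_depth) & (dosage != MISSING)
                dosage[low] = MISSING
            mean_depth = float("nan")
            if col_depth is not None:
                called = dosage != MISSING
                if called.any():
                    mean_depth = float(col_depth[called].mean())
            loci.append(Locus(v.CHROM, v.POS, ref, alt, mean_depth))
            call_cols.append(dosage)
            depth_cols.append(col_depth if col_depth is not None else np.zeros(n, dtype=np.int64))
    except VcfFormatError:
        raise
    except Exception as exc:
        raise VcfFormatError(f"malformed VCF record in {path!r}: {exc}") from exc

    if n_nonsnp:
        log.info("dropped %d non-bi-allelic/non-SNP records", n_nonsnp)
    if not have_depth:
        log.warning("no FORMAT/DP in %s; min-depth rule skipped", path)

    calls = (
        np.stack(call_cols, axis=1) if call_cols else np.empty((n, 0), dtype=np.int8)
    )
    depth = (
        np.stack(depth_cols, axis=1).astype(np.int32)
        if (depth_cols and have_depth)
        else None
    )

    # sort by (chrom, pos); drop coordinate duplicates keeping the first
    order = sorted(range(len(loci)), key=lambda i: (loci[i].chrom, loci[i].pos))
    seen: set[tuple[str, int]] = set()
    keep: list[int] = []
    for i in order:
        key = (loci[i].chrom, loci[i].pos)
        if key in seen:
            log.warning("duplicate coordinate %s:%d dropped", *key)
            continue
        seen.add(key)
        keep.append(i)

    return GenotypeMatrix(
        sample_ids=samples,
        loci=[loci[i] for i in keep],
        calls=calls[:, keep],
        depth=None if depth is None else depth[:, keep],
    )


def write_matrix(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a matrix back out as a VCF 4.2 text file.

    Dosage is re-encoded as unphased GT (``0/0``, ``0/1``, ``1/1``, ``./.``);
    the depth table, when present, is written as FORMAT/DP.  Reading the file
    back reproduces calls, coordinates and sample order exactly.
    """
    path = Path(path)
    contigs = sorted({l.chrom for l in g.loci})
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=clonekin\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if g.depth is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.sample_ids)
            + "\n"
        )
        fmt = "GT:DP" if g.depth is not None else "GT"
        for j, locus in enumerate(g.loci):
            cells = []
            for i in range(g.n_samples):
                gt = _GT_STRINGS[int(g.calls[i, j])]
                if g.depth is not None:
                    cells.append(f"{gt}:{int(g.depth[i, j])}")
                else:
                    cells.append(gt)
            fh.write(
                f"{locus.chrom}\t{locus.pos}\t.\t{locus.ref}\t{locus.alt}\t.\t.\t.\t{fmt}\t"
                + "\t".join(cells)
                + "\n"
            )


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read a delimited sample-metadata table.

    Expects a header with at least ``sample_id``; recognised annotation
    columns are ``species``, ``origin`` and ``harvest``.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if "sample_id" not in df.columns:
        raise VcfFormatError(f"metadata table {path!r} lacks a sample_id column")
    if df["sample_id"].duplicated().any():
        raise SampleIdentityError(f"duplicate sample ids in metadata {path!r}")
    return df
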