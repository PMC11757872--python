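"""Genotype containers, VCF input/output and marker quality control.

Genotypes are biallelic SNP dosages (count of the alternate allele, 0/1/2)
with per-entry read depths split into reference and alternate allele counts,
the natural representation of GBS (genotyping-by-sequencing) data carried in
VCF ``GT`` and ``AD`` FORMAT fields.

Marker filters mirror the standard GBS screen for an outcrossing
allotetraploid panel: minor allele frequency, per-marker missing rate and a
Hardy–Weinberg disequilibrium statistic whose strongly negative values
(heterozygote excess) flag collapsed homoeologous loci.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = -1  # dosage sentinel


@dataclass
class GenotypeData:
    """Dosage matrix plus per-entry allele read depths.

    Attributes
    ----------
    dosage : (n, m) int8 array
        Alternate-allele count per individual and marker; ``-1`` = missing.
    ref_reads, alt_reads : (n, m) int arrays
        Allele depths; ``depth = ref_reads + alt_reads``.
    marker_info : DataFrame with columns id, chrom, pos, ref, alt.
    sample_ids : ordered list of sample names.
    has_depth : False when the source VCF carried no AD field, in which case
        depth-aware methods (KGD) must not be used.
    """

    dosage: np.ndarray
    ref_reads: np.ndarray
    alt_reads: np.ndarray
    marker_info: pd.DataFrame
    sample_ids: list[str]
    has_depth: bool = True

    def __post_init__(self) -> None:
        n, m = self.dosage.shape
        if self.ref_reads.shape != (n, m) or self.alt_reads.shape != (n, m):
            raise ValueError("read matrices must match dosage shape")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length must match dosage rows")
        if len(self.marker_info) != m:
            raise ValueError("marker_info length must match dosage columns")
        if self.marker_info["id"].duplicated().any():
            raise ValueError("marker ids must be unique")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    @property
    def depth(self) -> np.ndarray:
        return self.ref_reads + self.alt_reads

    def dosage_float(self) -> np.ndarray:
        """Dosage as float with NaN for missing calls."""
        d = self.dosage.astype(float)
        d[self.dosage == MISSING] = np.nan
        return d

    def subset(self, markers=None, samples=None) -> "GenotypeData":
        """Return a copy restricted to marker and/or sample index arrays."""
        mi = np.arange(self.n_markers) if markers is None else np.asarray(markers)
        si = np.arange(self.n_samples) if samples is None else np.asarray(samples)
        return GenotypeData(
            dosage=self.dosage[np.ix_(si, mi)].copy(),
            ref_reads=self.ref_reads[np.ix_(si, mi)].copy(),
            alt_reads=self.alt_reads[np.ix_(si, mi)].copy(),
            marker_info=self.marker_info.iloc[mi].reset_index(drop=True),
            sample_ids=[self.sample_ids[i] for i in si],
            has_depth=self.has_depth,
        )

    # ------------------------------------------------------------------ I/O

    def write_vcf(self, path) -> None:
        """Write a VCF 4.2 file with GT and AD FORMAT fields."""
        info = self.marker_info
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##source=clovergs\n")
            for chrom in pd.unique(info["chrom"]):
                fh.write(f"##contig=<ID={chrom}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write(
                '##FORMAT=<ID=AD,Number=R,Type=Integer,'
                'Description="Allelic depths for the ref and alt alleles">\n'
            )
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.sample_ids)
                + "\n"
            )
            gt_codes = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
            for j in range(self.n_markers):
                row = info.iloc[j]
                cells = []
                for i in range(self.n_samples):
                    gt = gt_codes[int(self.dosage[i, j])]
                    cells.append(f"{gt}:{self.ref_reads[i, j]},{self.alt_reads[i, j]}")
                fh.write(
                    f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['ref']}\t"
                    f"{row['alt']}\t.\t.\t.\tGT:AD\t" + "\t".join(cells) + "\n"
                )


def read_vcf(path) -> GenotypeData:
    """Read biallelic SNPs from a VCF 4.x file into a :class:`GenotypeData`.

    Multi-allelic records and indels are skipped (counted in the log).  When
    the AD FORMAT field is absent the depth matrices are zero and
    ``has_depth`` is False.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    dosages, refs, alts, rows = [], [], [], []
    n_skipped = 0
    saw_ad = False
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        # gts012: 0/1/2 = alt dosage, 3 = missing
        gt = np.asarray(var.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING
        dosages.append(gt)
        try:
            ad = var.format("AD")
        except KeyError:
            ad = None
        if ad is not None:
            saw_ad = True
            ad = np.asarray(ad, dtype=np.int64)
            ad[ad < 0] = 0  # cyvcf2 encodes '.' as negative
            refs.append(ad[:, 0])
            alts.append(ad[:, 1])
        else:
            refs.append(np.zeros(len(samples), dtype=np.int64))
            alts.append(np.zeros(len(samples), dtype=np.int64))
        rows.append(
            (var.ID or f"{var.CHROM}_{var.POS}", var.CHROM, var.POS, var.REF, var.ALT[0])
        )
    if n_skipped:
        log.info("read_vcf: skipped %d multi-allelic/indel records", n_skipped)
    if not rows:
        raise ValueError(f"no biallelic SNP records found in {path}")
    info = pd.DataFrame(rows, columns=["id", "chrom", "pos", "ref", "alt"])
    return GenotypeData(
        dosage=np.asarray(dosages, dtype=np.int8).T.copy(),
        ref_reads=np.asarray(refs).T.copy(),
        alt_reads=np.asarray(alts).T.copy(),
        marker_info=info,
        sample_ids=samples,
        has_depth=saw_ad,
    )


# ---------------------------------------------------------------- statistics


def marker_stats(g: GenotypeData) -> pd.DataFrame:
    """Per-marker MAF, call rate and Hardy–Weinberg disequilibrium.

    HWdis is the observed major-homozygote frequency minus the squared
    major-allele frequency, ``f(AA) - p^2``, computed from naive genotype
    calls.  Heterozygote excess — the signature of a collapsed homoeologous
    locus in an allotetraploid — drives the statistic negative (to -0.25 when
    every call is heterozygous at p = 0.5).

    Returns a DataFrame indexed like ``marker_info`` with columns
    ``maf``, ``call_rate``, ``hwdis`` and ``flagged`` (True when the marker
    has no non-missing calls and its statistics are undefined).
    """
    d = g.dosage_float()
    called = ~np.isnan(d)
    n_called = called.sum(axis=0)
    call_rate = n_called / g.n_samples

    with np.errstate(invalid="ignore"):
        alt_freq = np.nansum(d, axis=0) / (2 * n_called)
    maf = np.minimum(alt_freq, 1 - alt_freq)

    # major-allele homozygote frequency
    major_is_ref = alt_freq <= 0.5
    hom_major = np.where(major_is_ref[None, :], d == 0, d == 2)
    with np.errstate(invalid="ignore"):
        f_hom_major = (hom_major & called).sum(axis=0) / n_called
    p_major = np.maximum(alt_freq, 1 - alt_freq)
    hwdis = f_hom_major - p_major**2

    flagged = n_called == 0
    return pd.DataFrame(
        {
            "id": g.marker_info["id"].to_numpy(),
            "maf": np.where(flagged, np.nan, maf),
            "call_rate": call_rate,
            "hwdis": np.where(flagged, np.nan, hwdis),
            "flagged": flagged,
        }
    )


@dataclass
class FilterReport:
    """Marker-filter bookkeeping with first-failing-rule attribution."""

    n_input: int
    n_retained: int
    removed_maf: int
    removed_missing: int
    removed_hwdis: int
    thresholds: dict = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return self.removed_maf + self.removed_missing + self.removed_hwdis


def apply_filters(
    g: GenotypeData,
    maf_min: float = 0.01,
    max_missing: float = 0.5,
    hwdis_min: float = -0.05,
) -> tuple[GenotypeData, FilterReport]:
    """Apply the MAF / missing-rate / HWdis marker screen.

    A marker is retained when ``maf >= maf_min`` and its missing fraction is
    ``<= max_missing`` and ``hwdis > hwdis_min``.  Removal counts are
    attributed to the first failing rule in the order MAF, missingness,
    HWdis; markers with undefined statistics (no calls) count as missing.
    """
    if not (0 <= maf_min <= 0.5):
        raise ValueError("maf_min must be in [0, 0.5]")
    if not (0 <= max_missing <= 1):
        raise ValueError("max_missing must be in [0, 1]")
    if not (-1 <= hwdis_min <= 1):
        raise ValueError("hwdis_min must be in [-1, 1]")

    stats = marker_stats(g)
    missing_frac = 1 - stats["call_rate"].to_numpy()
    maf = stats["maf"].to_numpy()
    hwdis = stats["hwdis"].to_numpy()
    flagged = stats["flagged"].to_numpy()

    fail_maf = ~flagged & (maf < maf_min)
    fail_missing = ~fail_maf & (flagged | (missing_frac > max_missing))
    fail_hwdis = ~fail_maf & ~fail_missing & ~(hwdis > hwdis_min)
    keep = ~(fail_maf | fail_missing | fail_hwdis)

    report = FilterReport(
        n_input=g.n_markers,
        n_retained=int(keep.sum()),
        removed_maf=int(fail_maf.sum()),
        removed_missing=int(fail_missing.sum()),
        removed_hwdis=int(fail_hwdis.sum()),
        thresholds={
            "maf_min": maf_min,
            "max_missing": max_missing,
            "hwdis_min": hwdis_min,
        },
    )
    return g.subset(markers=np.flatnonzero(keep)), report
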