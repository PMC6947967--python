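"""VCF import/export for called genotypes (GT) and dosages (DS).

Loci are written as chr<N>:pos with synthetic alleles REF=A (code 0
allele "a") and ALT=T (allele "A"); the genotype code counts ALT alleles,
so GT 0/0 = aa = 0, 0/1 = Aa = 1, 1/1 = AA = 2, ./. = missing.  Dosage
matrices are stored in the per-sample DS FORMAT field.
"""
from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
import pysam

from .gbs import MISSING

__all__ = ["write_vcf", "read_vcf"]

_GT = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}


def _header(chroms: Sequence[int], chrom_lengths: Optional[dict],
            samples: Sequence[str], dosage: bool) -> pysam.VariantHeader:
    h = pysam.VariantHeader()
    for c in sorted(set(int(x) for x in chroms)):
        length = None if chrom_lengths is None else chrom_lengths.get(c)
        if length:
            h.add_line(f"##contig=<ID=chr{c + 1},length={length}>")
        else:
            h.add_line(f"##contig=<ID=chr{c + 1}>")
    h.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    if dosage:
        h.add_line('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Expected ALT dosage">')
    for s in samples:
        h.add_sample(s)
    return h


def write_vcf(path: str, chrom: np.ndarray, pos_bp: np.ndarray,
              data: np.ndarray, samples: Optional[Sequence[str]] = None,
              chrom_lengths: Optional[dict] = None) -> None:
    """Write a (n_samples, n_loci) matrix as VCF.

    Integer matrices (missing = -1) are written as GT; float matrices
    (missing = NaN) as DS with a best-guess GT.
    """
    data = np.asarray(data)
    dosage = np.issubdtype(data.dtype, np.floating)
    n, m = data.shape
    if m != len(pos_bp):
        raise ValueError("data columns must match loci")
    if samples is None:
        samples = [f"ind{i}" for i in range(n)]
    header = _header(chrom, chrom_lengths, samples, dosage)
    with pysam.VariantFile(path, "w", header=header) as out:
        for j in range(m):
            rec = out.new_record(contig=f"chr{int(chrom[j]) + 1}",
                                 start=int(pos_bp[j]) - 1, alleles=("A", "T"))
            col = data[:, j]
            for i, s in enumerate(samples):
                if dosage:
                    v = col[i]
                    if np.isnan(v):
                        rec.samples[s]["GT"] = (None, None)
                    else:
                        rec.samples[s]["GT"] = _GT[int(round(float(v))) if v == round(v) else
                                                   (0 if v < 0.5 else (1 if v < 1.5 else 2))]
                        rec.samples[s]["DS"] = float(v)
                else:
                    rec.samples[s]["GT"] = _GT[int(col[i])]
            out.write(rec)


def read_vcf(path: str, field: str = "GT"
             ) -> Tuple[np.ndarray, np.ndarray, np.ndarray, list]:
    """Read a VCF back into (chrom, pos_bp, matrix, samples).

    ``field`` "GT" yields an int8 call matrix (missing = -1); "DS" a float
    dosage matrix (missing = NaN).
    """
    if field not in ("GT", "DS"):
        raise ValueError("field must be 'GT' or 'DS'")
    chroms, poss, rows = [], [], []
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            name = rec.chrom
            c = int(name[3:]) - 1 if name.startswith("chr") else int(name) - 1
            chroms.append(c)
            poss.append(rec.pos)
            if field == "GT":
                row = []
                for s in samples:
                    gt = rec.samples[s].get("GT")
                    if gt is None or any(a is None for a in gt):
                        row.append(MISSING)
                    else:
                        row.append(sum(gt))
                rows.append(np.asarray(row, dtype=np.int8))
            else:
                row = []
                for s in samples:
                    ds = rec.samples[s].get("DS")
                    row.append(np.nan if ds is None else float(ds))
                rows.append(np.asarray(row, dtype=np.float64))
    if not rows:
        raise ValueError(f"no records in {path}")
    matrix = np.stack(rows, axis=1)
    return (np.asarray(chroms, dtype=np.int16), np.asarray(poss, dtype=np.int64),
            matrix, samples)
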