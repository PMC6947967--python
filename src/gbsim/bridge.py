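"""Bridge to external genotype imputers via VCF round-trips.

The heavy-duty haplotype imputers used in practice (Beagle, IMPUTE2,
FImpute) are third-party binaries; this module only shuttles data to and
from them.  The command template receives ``{input}`` and ``{output}``
placeholders; the imputer must return a VCF covering exactly the same
loci (matched on chromosome + position).
"""
from __future__ import annotations

import shlex
import subprocess
from pathlib import Path

import numpy as np

from . import vcfio

__all__ = ["ExternalImputerUnavailable", "external_imputer_bridge"]


class ExternalImputerUnavailable(RuntimeError):
    """Raised when the configured imputer command cannot be run."""


def external_imputer_bridge(calls: np.ndarray, chrom: np.ndarray,
                            pos_bp: np.ndarray, command: str, workdir: str,
                            field: str = "GT") -> np.ndarray:
    """Write calls to VCF, run the imputer command, read the result back.

    Returns a dosage matrix (float, GT results are promoted to dosage).
    Raises :class:`ExternalImputerUnavailable` if the command cannot be
    executed, and ValueError if the output loci do not align.
    """
    wd = Path(workdir)
    wd.mkdir(parents=True, exist_ok=True)
    vcf_in = wd / "bridge_in.vcf"
    vcf_out = wd / "bridge_out.vcf"
    vcfio.write_vcf(str(vcf_in), chrom, pos_bp, calls)
    cmd = command.format(input=shlex.quote(str(vcf_in)),
                         output=shlex.quote(str(vcf_out)))
    try:
        proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
    except OSError as exc:  # pragma: no cover - environment-specific
        raise ExternalImputerUnavailable(f"cannot run imputer command: {exc}") from exc
    if proc.returncode != 0:
        raise ExternalImputerUnavailable(
            f"imputer command failed (exit {proc.returncode}): {proc.stderr.strip()[:500]}")
    if not vcf_out.exists():
        raise ExternalImputerUnavailable("imputer produced no output VCF")
    out_chrom, out_pos, matrix, _ = vcfio.read_vcf(str(vcf_out), field=field)
    if len(out_pos) != len(pos_bp) or np.any(out_chrom != chrom) or np.any(out_pos != pos_bp):
        raise ValueError("imputer output loci do not align with the input panel")
    matrix = matrix.astype(np.float64)
    if field == "GT":
        matrix[matrix < 0] = np.nan
    return matrix
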