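"""Study configuration: genome map, population design, QC and scenario settings.

The defaults describe the simulated livestock design used throughout the
package: a 5 x 100 cM genome with a dense, evenly spaced bi-allelic marker
grid, a long random-mating historical phase establishing mutation--drift
equilibrium, a bottleneck, one expanded generation, and ten recent
generations bred under EBV-based truncation selection.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import yaml


@dataclass(frozen=True)
class GenomeSpec:
    """Genome layout and mutation model.

    The marker grid is "evenly spaced": with 1 cM = 1 Mb and 10**6 marker
    loci on a 100 cM chromosome, adjacent grid positions are 100 bp apart.
    Recurrent mutation flips an allele with the given per-locus, per-gamete
    probability (active in the historical phases only).
    """

    n_chromosomes: int = 5
    chrom_length_cm: float = 100.0
    bp_per_cm: int = 1_000_000
    grid_spacing_bp: int = 100
    n_qtl_per_chrom: int = 100
    marker_mutation_rate: float = 2.5e-5
    qtl_mutation_rate: float = 2.5e-5
    qtl_gamma_shape: float = 0.4

    def __post_init__(self) -> None:
        if self.n_chromosomes <= 0 or self.n_qtl_per_chrom <= 0:
            raise ValueError("counts must be positive")
        if self.chrom_length_cm <= 0 or self.bp_per_cm <= 0 or self.grid_spacing_bp <= 0:
            raise ValueError("lengths must be positive")
        for r in (self.marker_mutation_rate, self.qtl_mutation_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("mutation rates must lie in [0, 1]")
        if self.qtl_gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")

    @property
    def chrom_length_bp(self) -> int:
        return int(round(self.chrom_length_cm * self.bp_per_cm))

    @property
    def n_marker_loci_per_chrom(self) -> int:
        return self.chrom_length_bp // self.grid_spacing_bp

    @property
    def genome_length_bp(self) -> int:
        return self.n_chromosomes * self.chrom_length_bp

    def with_mutation_scaled(self, scale: float) -> "GenomeSpec":
        """Inflate mutation rates by 1/scale so that 4*N*mu is preserved when
        population sizes are shrunk by ``scale`` (see PopulationDesign.scaled)."""
        if scale <= 0:
            raise ValueError("scale must be positive")
        return dataclasses.replace(
            self,
            marker_mutation_rate=min(1.0, self.marker_mutation_rate / scale),
            qtl_mutation_rate=min(1.0, self.qtl_mutation_rate / scale),
        )


def _even(x: float, minimum: int = 4) -> int:
    """Round to the nearest even integer, at least ``minimum``."""
    n = max(minimum, int(round(x)))
    return n if n % 2 == 0 else n + 1


@dataclass(frozen=True)
class PopulationDesign:
    """Population structure: historical drift phases, bottleneck founders,
    one expanded generation, and EBV-selected recent generations."""

    hist_phase1_generations: int = 1000
    hist_phase1_size: int = 2000
    hist_phase2_generations: int = 200
    hist_phase2_end_size: int = 400
    founder_males: int = 40
    founder_females: int = 200
    expand_generations: int = 1
    litter_size: int = 5
    recent_sires: int = 100
    recent_dams: int = 500
    recent_generations: int = 10
    sire_replacement: float = 0.8
    dam_replacement: float = 0.4
    heritability: float = 0.3
    phenotypic_variance: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.heritability < 1.0:
            raise ValueError("heritability must lie in (0, 1)")
        for f in (self.sire_replacement, self.dam_replacement):
            if not 0.0 <= f <= 1.0:
                raise ValueError("replacement fractions must lie in [0, 1]")
        if self.phenotypic_variance <= 0:
            raise ValueError("phenotypic variance must be positive")
        counts = (
            self.hist_phase1_generations, self.hist_phase1_size,
            self.hist_phase2_generations, self.hist_phase2_end_size,
            self.founder_males, self.founder_females, self.litter_size,
            self.recent_sires, self.recent_dams, self.recent_generations,
        )
        if any(c <= 0 for c in counts):
            raise ValueError("all design counts must be positive")

    @property
    def residual_variance(self) -> float:
        return self.phenotypic_variance * (1.0 - self.heritability)

    def scaled(self, scale: float) -> "PopulationDesign":
        """Shrink the historical phases by ``scale``, preserving their
        cumulative drift (sum over generations of 1/2N).

        Phase 1 scales generations and size jointly (G/2N invariant).
        Phase 2 keeps its end size — the bottleneck, founder sample,
        expansion and recent breeding design are never scaled, since their
        drift and selection behaviour is what the study measures — and its
        generation count is chosen so the phase-2 drift integral matches
        the full design.  Pair with GenomeSpec.with_mutation_scaled so the
        mutation-drift balance (4*N*mu) is preserved as well.
        """
        if scale <= 0 or scale > 1:
            raise ValueError("scale must lie in (0, 1]")
        if scale == 1.0:
            return self
        import numpy as np
        n1 = _even(self.hist_phase1_size * scale)
        g1 = max(1, int(round(self.hist_phase1_generations * scale)))
        end = self.hist_phase2_end_size
        # full-design phase-2 drift integral
        full = np.linspace(self.hist_phase1_size, end, self.hist_phase2_generations + 1)[1:]
        target = float(np.sum(1.0 / (2.0 * full)))
        shape = np.linspace(n1, end, 513)[1:]
        per_gen = float(np.mean(1.0 / (2.0 * shape)))
        g2 = max(1, int(round(target / per_gen)))
        return dataclasses.replace(
            self,
            hist_phase1_generations=g1,
            hist_phase1_size=n1,
            hist_phase2_generations=g2,
        )


#: MAF editing criteria investigated in the study (None = no MAF limit).
MAF_CRITERIA: Tuple[Optional[float], ...] = (None, 0.001, 0.01, 0.03)


@dataclass(frozen=True)
class QCConfig:
    """Marker editing: call-rate threshold and one of the MAF criteria."""

    call_rate_threshold: float = 0.8
    call_rate_axis: str = "loci"  # "loci" | "individuals" | "both"
    maf_threshold: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.call_rate_threshold <= 1.0:
            raise ValueError("call-rate threshold must lie in [0, 1]")
        if self.call_rate_axis not in ("loci", "individuals", "both"):
            raise ValueError("call_rate_axis must be 'loci', 'individuals' or 'both'")
        if self.maf_threshold is not None and not 0.0 <= self.maf_threshold <= 0.5:
            raise ValueError("MAF threshold must lie in [0, 0.5]")


@dataclass(frozen=True)
class ScenarioConfig:
    """Full factorial study grid: replicates x depths x MAF criteria x variants."""

    depths: Tuple[float, ...] = (2, 4, 5, 10)
    maf_criteria: Tuple[Optional[float], ...] = MAF_CRITERIA
    variants: Tuple[str, ...] = ("GBS", "Gc", "GcRounded", "GBSr")
    n_replicates: int = 10
    master_seed: int = 1
    scale_factor: float = 1.0
    predict: bool = True
    train_size: int = 7500
    test_size: int = 2500
    mask_reads_upto: int = 0  # set calls with 1 <= reads <= k missing before QC

    def __post_init__(self) -> None:
        if not self.depths or not self.maf_criteria or not self.variants:
            raise ValueError("depths, maf_criteria and variants must be non-empty")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if any(x <= 0 for x in self.depths):
            raise ValueError("mean depths must be positive")


def load_config(path: str) -> tuple[GenomeSpec, PopulationDesign, ScenarioConfig]:
    """Read a YAML study configuration (any subset of the three sections)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    spec = GenomeSpec(**raw.get("genome", {}))
    maf = raw.get("scenario", {}).pop("maf_criteria", None)
    scen_kwargs = raw.get("scenario", {})
    if maf is not None:
        scen_kwargs["maf_criteria"] = tuple(None if m in ("none", None) else float(m) for m in maf)
    for key in ("depths", "variants"):
        if key in scen_kwargs:
            scen_kwargs[key] = tuple(scen_kwargs[key])
    design = PopulationDesign(**raw.get("population", {}))
    scenario = ScenarioConfig(**scen_kwargs)
    return spec, design, scenario


def save_config(path: str, spec: GenomeSpec, design: PopulationDesign,
                scenario: ScenarioConfig) -> None:
    payload = {
        "genome": dataclasses.asdict(spec),
        "population": dataclasses.asdict(design),
        "scenario": {**dataclasses.asdict(scenario),
                     "maf_criteria": ["none" if m is None else m for m in scenario.maf_criteria],
                     "depths": list(scenario.depths),
                     "variants": list(scenario.variants)},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
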