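"""Pipeline configuration.

Every analysis threshold is named here with its study default so a run is
fully described by one object.  MCMC/permutation counts default to the
published protocol sizes; `Config.reduced()` gives the desk-scale settings
used by the bundled examples and tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class Config:
    seed: int = 0

    # zygosity calling from per-genotype allele fractions
    hom_max_fraction: float = 0.25   # < 0.25 (or > 0.75) => homozygous
    het_lo: float = 0.40             # [0.40, 0.60] => heterozygous
    het_hi: float = 0.60

    # site / sample filters
    maf_lo: float = 0.05
    maf_hi: float = 0.95
    max_site_missing: float = 0.20
    min_depth: int = 3
    max_sample_missing: float = 0.30

    # SNP classification
    blosum_matrix: str = "BLOSUM62"
    conservative_min_score: float = 1.0
    rare_lo: float = 0.25            # wild-type freq <=0.25 or >=0.75 => rare
    rare_hi: float = 0.75
    balanced_lo: float = 0.40        # [0.40, 0.60] => balanced
    balanced_hi: float = 0.60
    prevalent_focal_min: float = 0.75
    prevalent_other_max: float = 0.25
    diagnostic_focal_min: float = 0.50
    diagnostic_other_max: float = 0.05
    ecotype_alpha: float = 0.05

    # structure / admixture
    k_min: int = 1
    k_max: int = 10
    n_burnin: int = 100_000
    n_iter: int = 100_000
    n_runs: int = 10
    admixture_alpha: float = 1.0
    membership_threshold: float = 0.70
    representative_threshold: float = 0.70
    run_selection: str = "highest"   # "highest" or "lowest" lnP(D) run

    # differentiation / AMOVA / spatial
    n_permutations: int = 999
    nei_distance_cap: float = 10.0
    lsa_permutations: int = 9999
    lsa_neighbors_min: int = 7
    lsa_neighbors_max: int = 14
    mantel_log_distance: bool = False

    # trees / dating
    n_bootstrap: int = 500
    tree_distance: str = "p"         # "p" or "mcl" (composite Tamura-Nei)
    calibration_mya: float = 13.0

    # phasing
    phase_max_iter: int = 1000
    phase_tol: float = 1e-6
    phase_restarts: int = 3

    # subgenome windows
    window_bp: int = 100
    contrast_min_mapped: float = 0.80

    @classmethod
    def reduced(cls, seed: int = 0) -> "Config":
        """Desk-scale settings: reduced MCMC (1k/2k), fewer runs/permutations."""
        return cls(
            seed=seed,
            k_max=3,
            n_burnin=1000,
            n_iter=2000,
            n_runs=2,
            n_permutations=199,
            lsa_permutations=199,
            n_bootstrap=100,
        )

    @classmethod
    def from_yaml(cls, path) -> "Config":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))
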