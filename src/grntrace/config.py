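"""Simulation and pipeline configuration objects plus seed management."""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np

#: Calpain activity per genotype. The wild type is the reference (a = 1);
#: the null and loop-deletion mutants carry no calpain activity, the LG3
#: deletion retains partial activity, and the overexpressor exceeds WT.
DEFAULT_GENOTYPES: Tuple[Tuple[str, float], ...] = (
    ("WT", 1.0),
    ("dek1", 0.0),
    ("dek1_loop", 0.0),
    ("dek1_lg3", 0.5),
    ("oex1", 2.0),
)

#: Seventeen binary phenotype traits of the moss 2D-to-3D transition, each
#: mapped to the genotype subset in which the trait state is TRUE. Synthetic
#: stand-ins for a factorial phenotyping table; names describe protonema,
#: bud and gametophore phenotypes of calpain mutants.
DEFAULT_TRAIT_CATALOG: Mapping[str, frozenset] = {
    "overbudding": frozenset({"dek1", "dek1_loop"}),
    "bud_count_high": frozenset({"dek1", "dek1_loop"}),
    "bud_arrest": frozenset({"dek1", "dek1_loop", "dek1_lg3"}),
    "no_gametophores": frozenset({"dek1", "dek1_loop"}),
    "delayed_gametophores": frozenset({"dek1_lg3"}),
    "small_gametophores": frozenset({"dek1_lg3", "oex1"}),
    "leaf_division_defect": frozenset({"dek1", "dek1_loop"}),
    "caulonema_reduced": frozenset({"oex1"}),
    "chloronema_dominant": frozenset({"dek1", "dek1_loop"}),
    "filament_branching_high": frozenset({"dek1", "dek1_loop"}),
    "protonema_dense": frozenset({"dek1", "dek1_loop", "dek1_lg3"}),
    "colony_compact": frozenset({"dek1", "dek1_loop"}),
    "slow_colony_expansion": frozenset({"dek1", "dek1_loop", "oex1"}),
    "apical_cell_swollen": frozenset({"dek1"}),
    "division_plane_defect": frozenset({"dek1", "dek1_loop"}),
    "rhizoid_reduced": frozenset({"oex1"}),
    "sporophyte_absent": frozenset({"dek1", "dek1_loop", "dek1_lg3"}),
}


@dataclass(frozen=True)
class SimConfig:
    """Study design of the synthetic benchmark.

    The defaults emulate the source study's design: five genotypes
    (WT, two calpain-null alleles, a partial-activity allele and an
    overexpressor) sampled at days 3, 5, 9, 12 and 14 in triplicate,
    a layered TF hierarchy, and post-translational attenuation of
    cleaved TFs with rate ``kappa`` per unit calpain activity.

    Parameters
    ----------
    seed
        Fully determines every generator output.
    n_tf, n_targets
        Regulator and non-regulator gene counts (desk scale by default).
    layers
        Depth of the TF hierarchy; layer-0 TFs have no parents.
    edges_per_target
        Inbound true edges per non-root gene. Default 1: with five
        sampling days the regulator curve space is low-dimensional, and a
        single regulator per gene keeps planted edge signs identifiable
        from marginal correlations.
    sign_fraction_negative
        Probability that a true edge is repressive.
    genotypes
        ``(name, a_g)`` pairs; ``a_g >= 0`` is calpain activity.
    kappa
        Protein attenuation rate: a cleaved TF retains activity
        ``exp(-kappa * a_g)`` in genotype ``g``.
    noise_sd
        SD of Gaussian noise on the log scale (ignored for counts).
    nb_dispersion
        If set, emit negative-binomial counts with this dispersion
        instead of Gaussian-on-log values.
    frac_tf_cleaved
        Fraction of TFs routed to N-degron degradation after cleavage.
    protein_length_range
        Min/max synthetic protein length (residues); min must fit the
        20-mer site window.
    trait_genotype_map
        Binary trait name -> genotype subset with the TRUE state.
    """

    seed: int = 0
    n_tf: int = 20
    n_targets: int = 300
    layers: int = 3
    edges_per_target: int = 1
    sign_fraction_negative: float = 0.5
    genotypes: Tuple[Tuple[str, float], ...] = DEFAULT_GENOTYPES
    days: Tuple[float, ...] = (3.0, 5.0, 9.0, 12.0, 14.0)
    replicates: int = 3
    kappa: float = 1.0
    noise_sd: float = 0.05
    nb_dispersion: Optional[float] = None
    frac_tf_cleaved: float = 0.5
    protein_length_range: Tuple[int, int] = (200, 500)
    trait_genotype_map: Mapping[str, frozenset] = field(
        default_factory=lambda: dict(DEFAULT_TRAIT_CATALOG)
    )

    def __post_init__(self) -> None:
        if self.n_tf < 1 or self.n_targets < 1 or self.layers < 1:
            raise ValueError("counts must be >= 1")
        if self.edges_per_target < 1 or self.replicates < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 <= self.sign_fraction_negative <= 1.0:
            raise ValueError("sign_fraction_negative must be in [0, 1]")
        if not 0.0 <= self.frac_tf_cleaved <= 1.0:
            raise ValueError("frac_tf_cleaved must be in [0, 1]")
        names = [g for g, _ in self.genotypes]
        if len(set(names)) != len(names):
            raise ValueError("genotype names must be unique")
        for g, a in self.genotypes:
            if a < 0:
                raise ValueError(f"negative calpain activity for genotype {g!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.nb_dispersion is not None and self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.kappa < 0:
            raise ValueError("kappa must be nonnegative")
        lo, hi = self.protein_length_range
        if lo > hi or lo < 1:
            raise ValueError("invalid protein_length_range")
        known = set(names)
        for trait, gs in self.trait_genotype_map.items():
            unknown = set(gs) - known
            if unknown:
                raise ValueError(
                    f"trait {trait!r} references unknown genotypes {sorted(unknown)}"
                )

    @property
    def genotype_activity(self) -> Mapping[str, float]:
        return dict(self.genotypes)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["trait_genotype_map"] = {
            t: sorted(gs) for t, gs in self.trait_genotype_map.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "genotypes" in d:
            d["genotypes"] = tuple((str(g), float(a)) for g, a in d["genotypes"])
        if "days" in d:
            d["days"] = tuple(float(x) for x in d["days"])
        if "protein_length_range" in d:
            d["protein_length_range"] = tuple(int(x) for x in d["protein_length_range"])
        if "trait_genotype_map" in d:
            d["trait_genotype_map"] = {
                t: frozenset(gs) for t, gs in d["trait_genotype_map"].items()
            }
        return cls(**d)


def stage_seed(base_seed: int, stage: str) -> int:
    """Derive a reproducible per-stage child seed from one global seed.

    Stages can thus be rerun in isolation and still match a full run.
    The result is < 2**31 so it is accepted by every downstream RNG.
    """
    ss = np.random.SeedSequence([int(base_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))
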