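"""Parameter-recovery experiments on synthetic cohorts.

Each experiment fixes one pedigree (~1500 individuals, one eigendecomposition
reused throughout), then repeatedly redraws genotypes and phenotypes under a
trait preset's variance composition and refits the nested polygenic models.
The replicate means of the unconditioned heritability, the proportion of it
removed by conditioning on SNP sets, and the cross-set decomposition are the
quantities the published analysis reports.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .pedigree import compute_kinship
from .synthetic_data import SimulationConfig, gene_drop, simulate_pedigree, simulate_phenotype, trait_preset
from .varcomp import KinshipEigen, fit_polygenic

__all__ = ["ScenarioResult", "prepare_pedigree", "run_recovery"]


@dataclass
class ScenarioResult:
    """Replicate-level estimates from one recovery experiment."""

    preset: str
    n: int  # cohort size
    n_reps: int
    h2_m1: np.ndarray  # unconditioned heritability, per replicate
    h2_m2: np.ndarray  # conditioned on the trait-specific SNP set
    h2_m3: np.ndarray  # conditioned on all SNP sets
    h2_m2_plus: dict[str, np.ndarray]  # model 2 + one foreign set at a time

    @property
    def mean_h2_m1_pct(self) -> float:
        return 100.0 * float(np.mean(self.h2_m1))

    @property
    def mean_prop_explained_12_pct(self) -> float:
        """Mean of 100*(h2_m1 - h2_m2)/h2_m1 over replicates."""
        return float(np.mean(100.0 * (self.h2_m1 - self.h2_m2) / self.h2_m1))

    @property
    def mean_prop_explained_23_pct(self) -> float:
        """Mean additional percent of model-1 h2 removed going model 2 -> 3."""
        return float(np.mean(100.0 * (self.h2_m2 - self.h2_m3) / self.h2_m1))

    def mean_cross_additional_pct(self, source: str) -> float:
        extra = self.h2_m2_plus[source]
        return float(np.mean(100.0 * (self.h2_m2 - extra) / self.h2_m1))


def prepare_pedigree(
    seed: int,
    cfg: SimulationConfig | None = None,
    size_range: tuple[int, int] = (1350, 1650),
):
    """Simulate one pedigree of the target size (~1500) and precompute its
    kinship eigendecomposition.  The branching process has a heavy-tailed
    size distribution, so draws are repeated until the realized cohort size
    falls in ``size_range``."""
    cfg = cfg or SimulationConfig(seed=seed)
    children = np.random.SeedSequence(seed).spawn(40)
    ped = None
    for ss in children:
        cand = simulate_pedigree(cfg, np.random.default_rng(ss))
        if size_range[0] <= len(cand) <= size_range[1]:
            ped = cand
            break
        if ped is None or abs(len(cand) - np.mean(size_range)) < abs(
            len(ped) - np.mean(size_range)
        ):
            ped = cand
    kin = compute_kinship(ped)
    return ped, kin, KinshipEigen.from_kinship(kin)


def run_recovery(
    preset: str,
    n_reps: int = 50,
    seed: int = 0,
    models: tuple[int, ...] = (1,),
    cross_sources: tuple[str, ...] = (),
    pedigree=None,
    reml: bool = True,
) -> ScenarioResult:
    """Run one recovery experiment.

    Parameters
    ----------
    preset
        Trait preset name (variance composition of the simulated phenotype).
    models
        Which nested models to fit per replicate: 1 (intercept only),
        2 (+ trait-specific SNP dosages), 3 (+ all simulated SNP dosages).
    cross_sources
        Foreign SNP-set source traits to add to model 2 one at a time.
    pedigree
        Optional (ped, kin, eigen) triple from :func:`prepare_pedigree`, to
        share one pedigree across experiments.
    """
    cfg = trait_preset(preset, seed=seed)
    ped, kin, eig = pedigree if pedigree is not None else prepare_pedigree(seed, cfg)
    n = len(ped)
    root = np.random.SeedSequence(
        entropy=seed, spawn_key=(zlib.crc32(preset.encode()) % 2**31,)
    )
    streams = root.spawn(n_reps)

    trait_source = preset.upper()
    # the trait's own SNP set = the one matching the preset name when present,
    # otherwise the first configured set
    own = trait_source if trait_source in {s.source_trait for s in cfg.snp_specs} else None
    if own is None and cfg.snp_specs:
        own = cfg.snp_specs[0].source_trait

    mafs, snp_cols, set_cols = [], [], {}
    for s in cfg.snp_specs:
        set_cols[s.source_trait] = list(s.snp_ids)
        snp_cols += list(s.snp_ids)
        mafs += [s.maf] * s.count

    h2_m1 = np.empty(n_reps)
    h2_m2 = np.full(n_reps, np.nan)
    h2_m3 = np.full(n_reps, np.nan)
    h2_plus = {src: np.full(n_reps, np.nan) for src in cross_sources}
    for r, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        dosages = (
            gene_drop(ped, mafs, rng, snp_ids=snp_cols) if cfg.snp_specs else None
        )
        y, _ = simulate_phenotype(eig, dosages, cfg, rng)
        yv = y.to_numpy()
        fit1 = fit_polygenic(yv, None, eig, compute_se=False, reml=reml)
        h2_m1[r] = fit1.h2_total
        if 2 in models or 3 in models or cross_sources:
            own_cols = set_cols[own] if own else []
            X2 = dosages[own_cols].to_numpy(dtype=float) if own_cols else None
            fit2 = fit_polygenic(yv, X2, eig, compute_se=False, reml=reml)
            h2_m2[r] = fit2.h2_total
            if 3 in models:
                X3 = dosages[snp_cols].to_numpy(dtype=float)
                h2_m3[r] = fit_polygenic(yv, X3, eig, compute_se=False, reml=reml).h2_total
            for src in cross_sources:
                cols = own_cols + [c for c in set_cols[src] if c not in own_cols]
                Xp = dosages[cols].to_numpy(dtype=float)
                h2_plus[src][r] = fit_polygenic(yv, Xp, eig, compute_se=False, reml=reml).h2_total
    return ScenarioResult(
        preset=preset, n=n, n_reps=n_reps,
        h2_m1=h2_m1, h2_m2=h2_m2, h2_m3=h2_m3, h2_m2_plus=h2_plus,
    )
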