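"""Synthetic family cohorts with known ground truth.

The generator emulates a genetically isolated, multigenerational population
founded by a limited number of individuals: a small founder pool, several
generations of within-population mating with occasional first-cousin
marriages and limited marrying-in, yielding an extended pedigree of roughly
1500 individuals with low but pervasive pairwise kinship (median of the
nonzero coefficients of order 0.004) and a skewed, partly nonzero
distribution of inbreeding coefficients.

Phenotypes are built as ``y = covariates + sum_s D_s b_s + g + e`` where
``g ~ N(0, 2*Phi*sigma2_g)`` is drawn through the matrix square root of the
relationship matrix, ``e`` is i.i.d. noise, and each SNP-set contribution
``D_s b_s`` uses gene-dropped dosages.  Every component is rescaled so its
*realized* sample variance equals the configured value exactly, which keeps
recovery experiments tight at a single cohort size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ecg_traits import EcgRecord, GLOBAL_EXCLUSION_FLAGS, LEADS
from .pedigree import Individual, KinshipResult, Pedigree, compute_kinship, validate_pedigree
from .varcomp import KinshipEigen

__all__ = [
    "SnpSetSpec",
    "SimulationConfig",
    "CohortBundle",
    "trait_preset",
    "TRAIT_PRESETS",
    "simulate_pedigree",
    "gene_drop",
    "simulate_phenotype",
    "simulate_ecg_cohort",
]


@dataclass(frozen=True)
class SnpSetSpec:
    """A set of trait-associated SNPs with a joint variance contribution."""

    source_trait: str
    count: int
    maf: float
    variance_fraction: float

    def __post_init__(self) -> None:
        if not 0 < self.maf <= 0.5:
            raise ValueError(f"maf must be in (0, 0.5], got {self.maf}")
        if self.variance_fraction < 0:
            raise ValueError("variance fraction must be nonnegative")
        if self.count < 1:
            raise ValueError("SNP set must contain at least one SNP")

    @property
    def snp_ids(self) -> tuple[str, ...]:
        return tuple(f"{self.source_trait}_{k:03d}" for k in range(1, self.count + 1))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Pedigree defaults target ~1500 individuals over six offspring
    generations.  ``mating_rate`` is the chance an adult reproduces;
    ``within_rate`` the chance a reproducing adult finds a mate inside the
    population (otherwise a spouse marries in as a new founder);
    ``consanguinity_rate`` the chance an in-population mating is
    preferentially with a first cousin.
    """

    n_founders: int = 50
    n_generations: int = 6
    mean_offspring: float = 3.0
    consanguinity_rate: float = 0.15
    mating_rate: float = 0.65
    within_rate: float = 0.5
    snp_specs: tuple[SnpSetSpec, ...] = ()
    sigma2_g: float = 0.4
    sigma2_e: float = 0.6
    total_variance: float = 1.0
    covariate_effects: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders < 2 or self.n_generations < 1:
            raise ValueError("need n_founders >= 2 and n_generations >= 1")
        if self.sigma2_g < 0 or self.sigma2_e <= 0:
            raise ValueError("sigma2_g must be >= 0 and sigma2_e > 0")
        total = self.sigma2_g + self.sigma2_e + sum(
            s.variance_fraction for s in self.snp_specs
        )
        if abs(total - self.total_variance) > 1e-9:
            raise ValueError(
                f"variance components sum to {total}, not the declared total "
                f"{self.total_variance}"
            )


def trait_preset(name: str, **overrides) -> SimulationConfig:
    """Study-condition presets mirroring each trait's variance composition:
    the unconditioned heritability equals the published estimate, the
    trait-specific SNP set carries the published Delta-h2(1->2), and for PR
    the cross-trait sets carry the published cross-phenotype share."""
    key = name.lower()
    if key not in TRAIT_PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(TRAIT_PRESETS)}")
    g, e, sets = TRAIT_PRESETS[key]
    cfg = SimulationConfig(
        sigma2_g=g,
        sigma2_e=e,
        snp_specs=tuple(SnpSetSpec(*s) for s in sets),
    )
    return replace(cfg, **overrides) if overrides else cfg


#: (sigma2_g, sigma2_e, [(source_trait, count, maf, variance_fraction), ...])
TRAIT_PRESETS: dict[str, tuple[float, float, list]] = {
    "qrs": (0.28, 0.66, [("QRS", 21, 0.3, 0.06)]),
    "qt": (0.3456, 0.64, [("QT", 36, 0.3, 0.0144)]),
    "pr": (
        0.368,
        0.60,
        [
            ("PR", 9, 0.3, 0.008),
            ("QRS", 21, 0.3, 0.020),
            ("QT", 36, 0.3, 0.002),
            ("12LS", 2, 0.3, 0.002),
        ],
    ),
    "12ls": (0.49, 0.51, []),
    "sl": (0.46, 0.54, []),
    "cv": (0.34, 0.66, []),
}

#: all four GWAS SNP sets (used when a full cohort bundle is generated)
ALL_SNP_SETS = (("QRS", 21, 0.3), ("QT", 36, 0.3), ("PR", 9, 0.3), ("12LS", 2, 0.3))


# ---------------------------------------------------------------------------
# pedigree simulation


def _first_cousins(a: str, b: str, parents: dict[str, tuple[str, str] | None]) -> bool:
    pa, pb = parents.get(a), parents.get(b)
    if pa is None or pb is None:
        return False
    if set(pa) & set(pb):  # siblings/half-siblings, not cousins
        return False
    ga = {g for p in pa if parents.get(p) for g in parents[p]}
    gb = {g for p in pb if parents.get(p) for g in parents[p]}
    return bool(ga & gb)


def _siblings(a: str, b: str, parents: dict) -> bool:
    pa, pb = parents.get(a), parents.get(b)
    return pa is not None and pb is not None and bool(set(pa) & set(pb))


def simulate_pedigree(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> Pedigree:
    """Random multigenerational pedigree under the configured mating scheme."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    for attempt in range(10):
        ped = _simulate_pedigree_once(cfg, rng)
        if ped is not None:
            return ped
    raise RuntimeError("pedigree went extinct in 10 attempts; raise mean_offspring")


def _simulate_pedigree_once(cfg: SimulationConfig, rng: np.random.Generator) -> Pedigree | None:
    rows: list[tuple[str, str, str, str]] = []
    parents: dict[str, tuple[str, str] | None] = {}
    counter = [0]

    def new_id() -> str:
        counter[0] += 1
        return f"I{counter[0]:05d}"

    def add(fa: str | None, mo: str | None, sex: str) -> str:
        iid = new_id()
        rows.append((iid, fa or "0", mo or "0", "1" if sex == "male" else "2"))
        parents[iid] = (fa, mo) if fa else None
        return iid

    adults = [
        add(None, None, "male" if k % 2 == 0 else "female")
        for k in range(cfg.n_founders)
    ]
    for _ in range(cfg.n_generations):
        males = [a for a in adults if rows[int(a[1:]) - 1][3] == "1"]
        females = [a for a in adults if rows[int(a[1:]) - 1][3] == "2"]
        rng.shuffle(males)
        rng.shuffle(females)
        free_f = list(females)
        couples: list[tuple[str, str]] = []
        for m in males:
            if rng.random() >= cfg.mating_rate:
                continue
            wife = None
            if free_f and rng.random() < cfg.within_rate:
                pool = free_f
                if rng.random() < cfg.consanguinity_rate:
                    cousins = [f for f in pool if _first_cousins(m, f, parents)]
                    if cousins:
                        pool = cousins
                eligible = [f for f in pool if not _siblings(m, f, parents)]
                if eligible:
                    wife = eligible[int(rng.integers(len(eligible)))]
                    free_f.remove(wife)
            if wife is None:
                wife = add(None, None, "female")  # spouse marries in
            couples.append((m, wife))
        for f in free_f:
            if rng.random() < cfg.mating_rate * (1.0 - cfg.within_rate):
                couples.append((add(None, None, "male"), f))
        children: list[str] = []
        for fa, mo in couples:
            for _ in range(rng.poisson(cfg.mean_offspring)):
                sex = "male" if rng.random() < 0.5 else "female"
                children.append(add(fa, mo, sex))
        if not children:
            return None
        adults = children
    return validate_pedigree(rows)


# ---------------------------------------------------------------------------
# gene dropping


def gene_drop(
    ped: Pedigree,
    mafs: Sequence[float],
    rng: np.random.Generator | int | None = None,
    snp_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Drop alleles down the pedigree: founders draw two Bernoulli(maf)
    alleles per SNP; children inherit one random allele from each parent.
    Returns an individuals x SNPs dosage frame with values in {0, 1, 2}."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    mafs = np.asarray(mafs, dtype=float)
    if np.any((mafs <= 0) | (mafs >= 1)):
        raise ValueError("minor allele frequencies must lie strictly in (0, 1)")
    n, m = len(ped), mafs.size
    alleles = np.empty((n, m, 2), dtype=np.int8)
    par = ped.parent_indices()
    for i in range(n):
        f, mo = par[i]
        if f < 0:
            alleles[i] = rng.random((m, 2)) < mafs[:, None]
        else:
            pick_f = rng.integers(2, size=m)
            pick_m = rng.integers(2, size=m)
            alleles[i, :, 0] = alleles[f, np.arange(m), pick_f]
            alleles[i, :, 1] = alleles[mo, np.arange(m), pick_m]
    dosages = alleles.sum(axis=2).astype(np.int64)
    cols = list(snp_ids) if snp_ids is not None else [f"snp_{k:03d}" for k in range(1, m + 1)]
    return pd.DataFrame(dosages, index=list(ped.ids), columns=cols)


def _scale_to(x: np.ndarray, target_var: float, what: str) -> np.ndarray:
    """Rescale so the realized sample variance equals ``target_var`` exactly."""
    if target_var == 0:
        return np.zeros_like(x)
    v = float(np.var(x, ddof=1))
    if v <= 0:
        raise ValueError(f"{what}: zero realized variance, cannot scale to {target_var}")
    return x * np.sqrt(target_var / v)


def simulate_phenotype(
    kin: "KinshipResult | KinshipEigen",
    dosages: pd.DataFrame | None,
    cfg: SimulationConfig,
    rng: np.random.Generator | int | None = None,
    covariate_values: pd.DataFrame | None = None,
) -> tuple[pd.Series, dict]:
    """Draw one phenotype with the configured variance composition.

    Returns the trait (indexed by individual id) and a truth record holding
    every component and its realized variance.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    eig = kin if isinstance(kin, KinshipEigen) else KinshipEigen.from_kinship(kin)
    ids = list(eig.ids)
    n = len(ids)
    g = eig.U @ (np.sqrt(eig.d) * rng.standard_normal(n))
    g = _scale_to(g, cfg.sigma2_g, "polygenic component")
    e = _scale_to(rng.standard_normal(n), cfg.sigma2_e, "residual component")
    y = g + e
    truth: dict = {
        "sigma2_g": cfg.sigma2_g,
        "sigma2_e": cfg.sigma2_e,
        "components": {"polygenic": g, "residual": e},
        "snp_effects": {},
        "realized_variance": {
            "polygenic": float(np.var(g, ddof=1)),
            "residual": float(np.var(e, ddof=1)),
        },
    }
    for spec in cfg.snp_specs:
        if dosages is None:
            raise ValueError("snp_specs configured but no dosages supplied")
        cols = [c for c in spec.snp_ids if c in dosages.columns]
        if len(cols) != spec.count:
            raise KeyError(
                f"dosage matrix lacks columns for SNP set {spec.source_trait}"
            )
        D = dosages.loc[ids, cols].to_numpy(dtype=float)
        D = D - D.mean(axis=0)
        b = rng.standard_normal(spec.count)
        comp = D @ b
        var_comp = float(np.var(comp, ddof=1))
        if spec.variance_fraction > 0 and var_comp <= 0:
            raise ValueError(
                f"SNP set {spec.source_trait}: requested variance "
                f"{spec.variance_fraction} but dosages carry none"
            )
        comp = _scale_to(comp, spec.variance_fraction, f"SNP set {spec.source_trait}")
        scale = np.sqrt(spec.variance_fraction / var_comp) if var_comp > 0 else 0.0
        y = y + comp
        truth["components"][f"snp_{spec.source_trait}"] = comp
        truth["snp_effects"][spec.source_trait] = dict(zip(cols, b * scale))
        truth["realized_variance"][f"snp_{spec.source_trait}"] = float(
            np.var(comp, ddof=1)
        )
    if cfg.covariate_effects and covariate_values is not None:
        for cov, beta in cfg.covariate_effects.items():
            if cov not in covariate_values.columns:
                continue
            z = covariate_values.loc[ids, cov].to_numpy(dtype=float)
            sd = z.std(ddof=1)
            if sd > 0:
                y = y + beta * (z - z.mean()) / sd
    return pd.Series(y, index=ids, name="trait"), truth


# ---------------------------------------------------------------------------
# full ECG cohort bundle


@dataclass
class CohortBundle:
    """Everything one pipeline run consumes, with the generating truth."""

    pedigree: Pedigree
    kinship: KinshipResult
    records: list[EcgRecord]
    covariates: pd.DataFrame
    dosages: pd.DataFrame
    catalog: pd.DataFrame
    traits: pd.DataFrame  # standardized true genetic phenotypes per trait
    truth: dict


_TRAIT_SCALE = {  # population-style mean/SD on the raw measurement scale
    "QRS": (97.0, 10.0),
    "QT": (410.0, 26.0),  # QTc scale, ms
    "PR": (152.3, 22.1),
    "SL": (2316.0, 680.0),
    "CV": (1172.6, 498.3),
    "12LS": (13670.0, 3551.6),
}

_FLAG_RATES = {
    "atrial_fibrillation": 0.004,
    "myocardial_infarction": 0.006,
    "bundle_branch_block": 0.004,
    "av_block": 0.002,
    "pacemaker": 0.001,
    "wpw": 0.001,
    "pregnancy": 0.003,
    "antiarrhythmic_or_digoxin": 0.003,
}

_DEFAULT_COV_EFFECTS = {"age": 0.15, "sex": 0.10, "bmi": 0.08, "height": 0.08, "heart_rate": -0.10}


def _make_catalog(rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    locus = 0
    for source, count, _maf in ALL_SNP_SETS:
        for k in range(1, count + 1):
            locus += 1
            rows.append(
                {
                    "id": f"{source}_{k:03d}",
                    "source_trait": source,
                    "locus": f"L{locus:03d}",
                    "pvalue": float(10 ** -(8.1 + 4.0 * rng.random())),
                }
            )
    return pd.DataFrame(rows)


def simulate_ecg_cohort(cfg: SimulationConfig) -> CohortBundle:
    """Generate a complete raw cohort: pedigree, gene-dropped dosages for all
    four GWAS SNP sets, per-trait phenotypes under each trait's preset
    variance composition, raw ECG columns back-solved so the derived traits
    reproduce the simulated ones, covariates, exclusion flags and a SNP
    catalog.  Fully reproducible from ``cfg.seed``."""
    root = np.random.SeedSequence(cfg.seed)
    keys = {
        name: np.random.default_rng(s)
        for name, s in zip(
            ["pedigree", "genotypes", "covariates", "flags", "catalog",
             "QRS", "QT", "PR", "SL", "CV", "12LS", "raw"],
            root.spawn(12),
        )
    }
    ped = simulate_pedigree(cfg, keys["pedigree"])
    kin = compute_kinship(ped)
    eig = KinshipEigen.from_kinship(kin)
    ids = list(ped.ids)
    n = len(ids)

    catalog = _make_catalog(keys["catalog"])
    mafs = []
    snp_ids = []
    for source, count, maf in ALL_SNP_SETS:
        mafs += [maf] * count
        snp_ids += [f"{source}_{k:03d}" for k in range(1, count + 1)]
    dosages = gene_drop(ped, mafs, keys["genotypes"], snp_ids=snp_ids)

    rng_c = keys["covariates"]
    sex = np.array(
        [1.0 if ind.sex == "male" else 0.0 for ind in ped]
    )
    unknown = np.array([ind.sex == "unknown" for ind in ped])
    sex[unknown] = (rng_c.random(unknown.sum()) < 0.5).astype(float)
    age = np.clip(rng_c.normal(47.2, 13.9, n), 16.0, 85.0)
    bmi = np.clip(rng_c.normal(26.6, 4.5, n), 15.5, 48.0)
    height = np.where(
        sex == 1.0, rng_c.normal(173.0, 7.0, n), rng_c.normal(162.0, 6.5, n)
    )
    heart_rate = np.clip(rng_c.normal(63.0, 10.5, n), 38.0, 115.0)
    covariates = pd.DataFrame(
        {"sex": sex, "age": age, "bmi": bmi, "height": height, "heart_rate": heart_rate},
        index=ids,
    )

    cov_effects = dict(cfg.covariate_effects) or dict(_DEFAULT_COV_EFFECTS)
    traits = {}
    truth: dict = {"seed": cfg.seed, "traits": {}}
    for trait in ("QRS", "QT", "PR", "SL", "CV", "12LS"):
        tcfg = trait_preset(trait.lower())
        eff = {k: v for k, v in cov_effects.items() if not (trait == "QT" and k == "heart_rate")}
        tcfg = replace(tcfg, covariate_effects=eff, seed=cfg.seed)
        y, t = simulate_phenotype(
            eig, dosages, tcfg, keys[trait], covariate_values=covariates
        )
        traits[trait] = y
        truth["traits"][trait] = {
            "sigma2_g": tcfg.sigma2_g,
            "sigma2_e": tcfg.sigma2_e,
            "snp_fractions": {s.source_trait: s.variance_fraction for s in tcfg.snp_specs},
            "realized_variance": t["realized_variance"],
        }
    traits = pd.DataFrame(traits)

    rng_f = keys["flags"]
    flags = {
        name: rng_f.random(n) < rate for name, rate in _FLAG_RATES.items()
    }
    flags["pregnancy"] &= sex == 0.0

    rng_r = keys["raw"]
    qrs_ms = _TRAIT_SCALE["QRS"][0] + _TRAIT_SCALE["QRS"][1] * traits["QRS"].to_numpy()
    qrs_ms = np.clip(qrs_ms, 50.0, None)
    qtc = _TRAIT_SCALE["QT"][0] + _TRAIT_SCALE["QT"][1] * traits["QT"].to_numpy()
    qt_ms = np.clip(qtc, 250.0, None) * np.sqrt(60.0 / heart_rate)
    pr_ms = np.clip(
        _TRAIT_SCALE["PR"][0] + _TRAIT_SCALE["PR"][1] * traits["PR"].to_numpy(), 60.0, None
    )
    axis = np.clip(rng_r.normal(40.0, 20.0, n), -175.0, 175.0)
    sl = np.clip(_TRAIT_SCALE["SL"][0] + _TRAIT_SCALE["SL"][1] * traits["SL"].to_numpy(), 200.0, None)
    cv = np.clip(_TRAIT_SCALE["CV"][0] + _TRAIT_SCALE["CV"][1] * traits["CV"].to_numpy(), 100.0, None)
    ls12 = _TRAIT_SCALE["12LS"][0] + _TRAIT_SCALE["12LS"][1] * traits["12LS"].to_numpy()

    records: list[EcgRecord] = []
    other_leads = ("I", "II", "III", "aVR", "aVF", "V2", "V4")
    for k, iid in enumerate(ids):
        v_sl = sl[k] / qrs_ms[k]
        v_cv = cv[k] / qrs_ms[k]
        amp: dict[str, tuple[float, float]] = {
            "V1": (0.0, 0.5 * v_sl),
            "V5": (0.5 * v_sl, 0.0),
            "V6": (0.4 * v_sl, 0.0),
            "aVL": (0.5 * v_cv, 0.0),
            "V3": (0.0, 0.5 * v_cv),
        }
        fixed_total = 1.4 * v_sl + 1.0 * v_cv
        target_total = max(ls12[k] / qrs_ms[k], fixed_total)  # floor: leads cannot be negative
        share = (target_total - fixed_total) / len(other_leads)
        for lead in other_leads:
            amp[lead] = (0.6 * share, 0.4 * share)
        assert set(amp) == set(LEADS)
        records.append(
            EcgRecord(
                id=iid,
                qrs_ms=float(qrs_ms[k]),
                qt_ms=float(qt_ms[k]),
                pr_ms=float(pr_ms[k]),
                heart_rate_bpm=float(heart_rate[k]),
                qrs_axis_deg=float(axis[k]),
                amp=amp,
                flags={name: bool(flags[name][k]) for name in GLOBAL_EXCLUSION_FLAGS},
            )
        )
    return CohortBundle(
        pedigree=ped,
        kinship=kin,
        records=records,
        covariates=covariates,
        dosages=dosages,
        catalog=catalog,
        traits=traits,
        truth=truth,
    )
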