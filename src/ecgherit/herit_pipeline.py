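"""Three-model SNP-conditioning analysis of trait heritability.

Per trait, three nested polygenic models are fitted on an identical
complete-case subset:

* model 1 — intercept only (covariates were already residualized out);
* model 2 — plus the trait-specific GWAS SNP dosages.  The LVH proxies
  (SL, CV, 12LS) have almost no genome-wide-significant hits of their own,
  but QRS duration is a component of each, so their model 2 carries the QRS
  SNPs (plus, for 12LS, its own two SNPs);
* model 3 — plus every catalog SNP.

``Delta h2`` between models, measured on the total-variance scale
(``h2_total``), quantifies how much heritability the conditioned SNPs
explain; the proportion explained is ``Delta h2 / h2(model 1)``.  Adding
SNPs can slightly *increase* the estimate, so negative values are reported
as such, never clamped.  A cross-phenotype decomposition adds each foreign
trait's SNP set to model 2 in turn to locate pleiotropic signal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ecg_traits import TRAITS
from .pedigree import KinshipResult
from .varcomp import KinshipEigen, VCFit, fit_polygenic, lrt_h2_zero, lrt_nested

__all__ = [
    "SnpCatalog",
    "VCModelSpec",
    "TraitReport",
    "HeritabilityReport",
    "select_index_snps",
    "build_model_specs",
    "run_three_models",
    "proportion_explained",
    "cross_phenotype_decomposition",
]

log = logging.getLogger(__name__)

#: catalog source traits with their own genome-wide-significant hits
CATALOG_TRAITS = ("QRS", "QT", "PR", "12LS")


@dataclass(frozen=True)
class SnpCatalog:
    """Index SNPs (one per locus) annotated by source trait and discovery P."""

    table: pd.DataFrame  # columns: id, source_trait, locus, pvalue

    def __post_init__(self) -> None:
        missing = {"id", "source_trait", "locus", "pvalue"} - set(self.table.columns)
        if missing:
            raise ValueError(f"catalog missing column(s): {sorted(missing)}")
        unknown = set(self.table["source_trait"]) - set(CATALOG_TRAITS)
        if unknown:
            raise ValueError(f"unrecognized source trait(s): {sorted(unknown)}")
        if self.table["locus"].duplicated().any():
            raise ValueError("catalog has multiple SNPs per locus; select index SNPs first")

    def snps_for(self, source_trait: str) -> list[str]:
        t = self.table
        return sorted(t.loc[t["source_trait"] == source_trait, "id"])

    @property
    def all_snps(self) -> list[str]:
        return sorted(self.table["id"])

    def __len__(self) -> int:
        return len(self.table)


def select_index_snps(
    catalog: pd.DataFrame, available: set[str] | None = None
) -> SnpCatalog:
    """Keep one index SNP per locus: minimum discovery P-value, ties broken
    by lexicographically smallest id.  SNPs absent from ``available`` (e.g.
    not genotyped) are dropped with a log entry."""
    if len(catalog) == 0:
        raise ValueError("empty SNP catalog")
    cat = catalog.copy()
    if available is not None:
        lost = cat.loc[~cat["id"].isin(available), "id"]
        for snp in lost:
            log.info("dropped: unavailable SNP %s", snp)
        cat = cat[cat["id"].isin(available)]
        if len(cat) == 0:
            raise ValueError("no catalog SNP is available in the dosage data")
    cat = cat.sort_values(["locus", "pvalue", "id"], kind="stable")
    kept = cat.groupby("locus", sort=False).head(1).reset_index(drop=True)
    return SnpCatalog(kept)


@dataclass(frozen=True)
class VCModelSpec:
    """Fixed-effect specification of one model for one trait."""

    trait: str
    model: int  # 1, 2 or 3
    snp_ids: tuple[str, ...]


def build_model_specs(trait: str, catalog: SnpCatalog) -> tuple[VCModelSpec, VCModelSpec, VCModelSpec]:
    """Model-1/2/3 fixed-effect sets for one trait (see module docstring)."""
    if trait not in TRAITS:
        raise ValueError(f"unknown trait {trait!r}")
    if len(catalog) == 0:
        raise ValueError("empty SNP catalog")
    if trait in CATALOG_TRAITS and trait != "12LS":
        m2 = catalog.snps_for(trait)
    elif trait == "12LS":
        m2 = sorted(set(catalog.snps_for("QRS")) | set(catalog.snps_for("12LS")))
    else:  # SL, CV: QRS SNPs stand in (QRS is a component of the product)
        m2 = catalog.snps_for("QRS")
    if not m2:
        raise ValueError(f"no catalog SNPs available for trait {trait!r} model 2")
    return (
        VCModelSpec(trait, 1, ()),
        VCModelSpec(trait, 2, tuple(m2)),
        VCModelSpec(trait, 3, tuple(catalog.all_snps)),
    )


def proportion_explained(h2_before: float, h2_after: float) -> float:
    """Percent of the earlier model's heritability removed by conditioning;
    may be negative (conditioning can nudge the estimate upward)."""
    if not h2_before > 0:
        raise ValueError("proportion explained undefined for h2_before <= 0")
    return 100.0 * (h2_before - h2_after) / h2_before


@dataclass
class TraitReport:
    """Model-1/2/3 results and their comparisons for one trait."""

    trait: str
    n: int
    fits: tuple[VCFit, VCFit, VCFit]
    n_snps: tuple[int, int, int]
    p_h2: tuple[float, float, float]  # boundary LRT of h2=0 per model
    delta_h2_12: float
    delta_h2_23: float
    prop_explained_12: float  # % of model-1 h2 removed going 1 -> 2
    prop_explained_23: float  # additional %, (m2 - m3) / m1
    p_delta_12: float
    p_delta_23: float
    cross_sets: dict[str, dict] = field(default_factory=dict)

    @property
    def h2(self) -> tuple[float, float, float]:
        return tuple(f.h2_total for f in self.fits)

    @property
    def h2_se(self) -> tuple[float, float, float]:
        return tuple(f.h2_se for f in self.fits)

    def row(self) -> dict:
        h2 = self.h2
        out = {
            "trait": self.trait,
            "n": self.n,
            "h2_m1": h2[0], "se_m1": self.fits[0].h2_se, "p_m1": self.p_h2[0],
            "h2_m2": h2[1], "se_m2": self.fits[1].h2_se, "p_m2": self.p_h2[1],
            "delta_h2_12": self.delta_h2_12,
            "p_delta_12": self.p_delta_12,
            "n_snps_m2": self.n_snps[1],
            "h2_m3": h2[2], "se_m3": self.fits[2].h2_se, "p_m3": self.p_h2[2],
            "delta_h2_23": self.delta_h2_23,
            "p_delta_23": self.p_delta_23,
            "prop_explained_12_pct": self.prop_explained_12,
            "prop_explained_23_pct": self.prop_explained_23,
        }
        for name, d in self.cross_sets.items():
            out[f"cross_{name}_additional_pct"] = d["additional_pct"]
            out[f"cross_{name}_p"] = d["p"]
        return out


@dataclass
class HeritabilityReport:
    """Per-trait three-model heritability decomposition."""

    rows: list[TraitReport]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([r.row() for r in self.rows])


def _complete_subset(y: pd.Series, dosages: pd.DataFrame, snp_ids: tuple[str, ...]) -> pd.Index:
    ok = y.notna()
    if snp_ids:
        missing = [s for s in snp_ids if s not in dosages.columns]
        if missing:
            raise KeyError(f"dosage matrix lacks SNP(s): {missing}")
        ok &= dosages.reindex(y.index)[list(snp_ids)].notna().all(axis=1)
    return y.index[ok]


def _fit_spec(
    spec: VCModelSpec,
    y: pd.Series,
    dosages: pd.DataFrame,
    eig: KinshipEigen,
    reml: bool = False,
) -> VCFit:
    X = None
    if spec.snp_ids:
        X = dosages.loc[list(y.index), list(spec.snp_ids)].to_numpy(dtype=float)
    return fit_polygenic(y.to_numpy(dtype=float), X, eig, reml=reml)


def _eigen_for(kin, keep: pd.Index) -> KinshipEigen:
    if isinstance(kin, KinshipEigen):
        if tuple(keep) == kin.ids:
            return kin
        raise ValueError(
            "precomputed eigendecomposition does not match the complete-case "
            "subset; pass the KinshipResult instead"
        )
    idx = {iid: k for k, iid in enumerate(kin.ids)}
    sel = np.array([idx[i] for i in keep])
    return KinshipEigen.from_kinship(kin.phi[np.ix_(sel, sel)], tuple(keep))


def run_three_models(
    trait: str,
    y: pd.Series,
    dosages: pd.DataFrame,
    catalog: SnpCatalog,
    kin: "KinshipResult | KinshipEigen",
    reml: bool = True,
    cross: bool = True,
) -> TraitReport:
    """Fit models 1/2/3 for one trait on the identical complete-case subset
    (intersection over the model-3 SNP set: individuals are dropped, never
    SNPs, so log-likelihoods stay comparable).

    With ``reml=True`` (default) the reported variance components and h2
    come from REML fits, which are free of the fixed-effect small-sample
    bias that otherwise deflates sigma2_g as SNP columns are added; every
    likelihood-ratio test is computed from ML fits regardless, since REML
    likelihoods are not comparable across fixed-effect sets.
    """
    specs = build_model_specs(trait, catalog)
    keep = _complete_subset(y, dosages, specs[2].snp_ids)
    y = y.loc[keep]
    eig = _eigen_for(kin, keep)
    fits = tuple(_fit_spec(s, y, dosages, eig, reml=reml) for s in specs)
    ml_fits = (
        tuple(_fit_spec(s, y, dosages, eig, reml=False) for s in specs)
        if reml
        else fits
    )
    if len({f.n for f in fits}) != 1:
        raise RuntimeError("sample-set drift between models")
    null_lls = [
        fit_polygenic(
            y.to_numpy(dtype=float),
            dosages.loc[keep, list(s.snp_ids)].to_numpy(dtype=float) if s.snp_ids else None,
            eig, reml=False, fix_h2=0.0, compute_se=False,
        ).loglik
        for s in specs
    ]
    p_h2 = tuple(lrt_h2_zero(f, ll0) for f, ll0 in zip(ml_fits, null_lls))
    h2 = [f.h2_total for f in fits]
    report = TraitReport(
        trait=trait,
        n=len(y),
        fits=fits,
        n_snps=tuple(len(s.snp_ids) for s in specs),
        p_h2=p_h2,
        delta_h2_12=h2[0] - h2[1],
        delta_h2_23=h2[1] - h2[2],
        prop_explained_12=proportion_explained(h2[0], h2[1]),
        prop_explained_23=100.0 * (h2[1] - h2[2]) / h2[0],
        p_delta_12=lrt_nested(ml_fits[1], ml_fits[0], df=len(specs[1].snp_ids)),
        p_delta_23=lrt_nested(
            ml_fits[2], ml_fits[1], df=len(specs[2].snp_ids) - len(specs[1].snp_ids)
        ),
    )
    if cross:
        report.cross_sets = cross_phenotype_decomposition(
            trait, y, dosages, catalog, eig,
            model2=(specs[1], fits[1], ml_fits[1], h2[0]), reml=reml,
        )
    return report


def cross_phenotype_decomposition(
    trait: str,
    y: pd.Series,
    dosages: pd.DataFrame,
    catalog: SnpCatalog,
    kin: "KinshipResult | KinshipEigen",
    model2: tuple[VCModelSpec, VCFit, VCFit, float] | None = None,
    reml: bool = True,
) -> dict[str, dict]:
    """Add each foreign source-trait SNP set to model 2 in turn.

    Returns, per foreign set, the additional percent of model-1 heritability
    explained (``100 * (h2_m2 - h2_m2+set) / h2_m1``) and the nested-LRT
    p-value against model 2 (always from ML fits).
    """
    if model2 is None:
        specs = build_model_specs(trait, catalog)
        keep = _complete_subset(y, dosages, specs[2].snp_ids)
        y = y.loc[keep]
        kin = _eigen_for(kin, keep)
        fit1 = _fit_spec(specs[0], y, dosages, kin, reml=reml)
        fit2 = _fit_spec(specs[1], y, dosages, kin, reml=reml)
        fit2_ml = _fit_spec(specs[1], y, dosages, kin, reml=False) if reml else fit2
        model2 = (specs[1], fit2, fit2_ml, fit1.h2_total)
    spec2, fit2, fit2_ml, h2_m1 = model2
    eig = kin if isinstance(kin, KinshipEigen) else _eigen_for(kin, y.index)
    out: dict[str, dict] = {}
    for source in CATALOG_TRAITS:
        foreign = [s for s in catalog.snps_for(source) if s not in spec2.snp_ids]
        if len(foreign) < len(catalog.snps_for(source)):
            dropped = len(catalog.snps_for(source)) - len(foreign)
            if dropped and foreign:
                warnings.warn(
                    f"{source} set overlaps model 2 by {dropped} SNP(s); deduplicated"
                )
        if not foreign:
            continue  # empty foreign set: no report row
        aug = VCModelSpec(trait, 2, tuple(spec2.snp_ids) + tuple(sorted(foreign)))
        fit_aug = _fit_spec(aug, y, dosages, eig, reml=reml)
        fit_aug_ml = _fit_spec(aug, y, dosages, eig, reml=False) if reml else fit_aug
        out[source] = {
            "n_snps_added": len(foreign),
            "h2": fit_aug.h2_total,
            "additional_pct": 100.0 * (fit2.h2_total - fit_aug.h2_total) / h2_m1,
            "p": lrt_nested(fit_aug_ml, fit2_ml, df=len(foreign)),
        }
    return out
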