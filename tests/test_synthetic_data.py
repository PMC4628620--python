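"""Generator: pedigree structure, gene dropping, exact variance scaling,
cohort bundle reproducibility."""

import numpy as np
import pytest

from ecgherit.ecg_traits import apply_exclusions, derived_trait
from ecgherit.pedigree import compute_kinship, validate_pedigree
from ecgherit.synthetic_data import (
    SimulationConfig,
    SnpSetSpec,
    gene_drop,
    simulate_ecg_cohort,
    simulate_pedigree,
    simulate_phenotype,
    trait_preset,
)
from ecgherit.varcomp import KinshipEigen


class TestSimulatePedigree:
    def test_no_within_mating_means_no_inbreeding(self):
        # every spouse marries in from outside: all parents unrelated
        cfg0 = SimulationConfig(n_founders=20, n_generations=3,
                                consanguinity_rate=0.0, within_rate=0.0, seed=2)
        ped0 = simulate_pedigree(cfg0, np.random.default_rng(2))
        assert np.all(compute_kinship(ped0).F == 0)

    def test_cousin_matings_produce_familiar_f_values(self):
        cfg = SimulationConfig(n_founders=40, n_generations=4,
                               consanguinity_rate=0.35, seed=3)
        ped = simulate_pedigree(cfg, np.random.default_rng(3))
        F = compute_kinship(ped).F
        assert (np.abs(F - 0.0625) < 1e-12).any()  # first-cousin offspring

    def test_default_config_matches_study_structure(self):
        cfg = SimulationConfig(seed=5)
        ped = simulate_pedigree(cfg, np.random.default_rng(5))
        kin = compute_kinship(ped)
        n = len(ped)
        assert 700 <= n <= 3000  # branching process spread around ~1500
        off = kin.phi[np.triu_indices(n, 1)]
        med = np.median(off[off > 0])
        assert 0.002 <= med <= 0.008  # median nonzero kinship ~ 0.004
        assert (kin.F > 0).any()

    def test_validates(self):
        cfg = SimulationConfig(n_founders=12, n_generations=2, seed=9)
        ped = simulate_pedigree(cfg, np.random.default_rng(9))
        # re-validating the emitted rows must succeed and preserve order
        rows = [
            (i.id, i.father or "0", i.mother or "0",
             {"male": "1", "female": "2"}.get(i.sex, "0"))
            for i in ped
        ]
        assert validate_pedigree(rows).ids == ped.ids


class TestGeneDrop:
    def test_maf_bounds(self, trio_ped):
        with pytest.raises(ValueError):
            gene_drop(trio_ped, [0.0])
        with pytest.raises(ValueError):
            gene_drop(trio_ped, [1.0])

    def test_founder_dosage_mean(self):
        ped = validate_pedigree([(f"f{k}", "0", "0", "1") for k in range(2000)])
        dos = gene_drop(ped, [0.5], np.random.default_rng(1))
        assert dos.iloc[:, 0].mean() == pytest.approx(1.0, abs=0.06)

    def test_homozygous_parents_transmit(self, trio_ped):
        rng = np.random.default_rng(0)
        for _ in range(20):
            dos = gene_drop(trio_ped, [0.05] * 30, rng)
            both_zero = (dos.loc["F"] == 0) & (dos.loc["M"] == 0)
            assert (dos.loc["C"][both_zero] == 0).all()

    def test_sibling_dosage_correlation(self):
        rows = [("F", "0", "0", "1"), ("M", "0", "0", "2"),
                ("S1", "F", "M", "1"), ("S2", "F", "M", "2")]
        ped = validate_pedigree(rows)
        dos = gene_drop(ped, [0.3] * 10_000, np.random.default_rng(4))
        r = np.corrcoef(dos.loc["S1"], dos.loc["S2"])[0, 1]
        assert r == pytest.approx(0.5, abs=0.03)


@pytest.fixture(scope="module")
def eig():
    cfg = SimulationConfig(n_founders=30, n_generations=3, seed=31)
    ped = simulate_pedigree(cfg, np.random.default_rng(31))
    return ped, KinshipEigen.from_kinship(compute_kinship(ped))


class TestSimulatePhenotype:
    def test_exact_variance_scaling(self, eig):
        ped, eig = eig
        cfg = trait_preset("pr")
        dosages = gene_drop(
            ped,
            [s.maf for s in cfg.snp_specs for _ in range(s.count)],
            np.random.default_rng(32),
            snp_ids=[c for s in cfg.snp_specs for c in s.snp_ids],
        )
        y, truth = simulate_phenotype(eig, dosages, cfg, np.random.default_rng(33))
        rv = truth["realized_variance"]
        assert rv["polygenic"] == pytest.approx(0.368, abs=1e-10)
        assert rv["residual"] == pytest.approx(0.600, abs=1e-10)
        assert rv["snp_PR"] == pytest.approx(0.008, abs=1e-12)
        assert rv["snp_QRS"] == pytest.approx(0.020, abs=1e-12)
        total = sum(np.var(c, ddof=1) for c in truth["components"].values())
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_pure_noise_recovers_zero_h2(self, eig):
        ped, eig = eig
        cfg = SimulationConfig(sigma2_g=1e-12, sigma2_e=1.0 - 1e-12)
        from ecgherit.varcomp import fit_polygenic

        h2s = []
        for r in range(10):
            y, _ = simulate_phenotype(eig, None, cfg, np.random.default_rng(300 + r))
            h2s.append(fit_polygenic(y.to_numpy(), None, eig, compute_se=False).h2)
        assert np.mean(h2s) < 0.08

    def test_configured_h2_is_realized(self, eig):
        ped, eig = eig
        cfg = SimulationConfig(sigma2_g=0.8, sigma2_e=1.2, total_variance=2.0)
        y, truth = simulate_phenotype(eig, None, cfg, np.random.default_rng(41))
        rv = truth["realized_variance"]
        assert rv["polygenic"] / (rv["polygenic"] + rv["residual"]) == pytest.approx(0.4, abs=1e-12)

    def test_missing_dosages_rejected(self, eig):
        ped, eig = eig
        cfg = trait_preset("qt")
        with pytest.raises(ValueError):
            simulate_phenotype(eig, None, cfg, np.random.default_rng(0))


@pytest.fixture(scope="module")
def bundle():
    cfg = SimulationConfig(n_founders=24, n_generations=3, seed=71)
    return simulate_ecg_cohort(cfg), cfg


class TestCohortBundle:
    def test_reproducible_from_seed(self, bundle):
        b1, cfg = bundle
        b2 = simulate_ecg_cohort(cfg)
        assert b1.pedigree.ids == b2.pedigree.ids
        assert b1.dosages.equals(b2.dosages)
        assert b1.traits.equals(b2.traits)
        assert all(
            r1 == r2 for r1, r2 in zip(b1.records, b2.records)
        )

    def test_derived_traits_match_simulated(self, bundle):
        b, _ = bundle
        from ecgherit.synthetic_data import _TRAIT_SCALE

        for trait in ("QRS", "PR", "SL", "CV", "QT"):
            mean, sd = _TRAIT_SCALE[trait]
            derived = np.array([derived_trait(r, trait) for r in b.records])
            target = mean + sd * b.traits[trait].to_numpy()
            if trait in ("QRS", "PR", "SL", "CV"):
                target = np.clip(target, {"QRS": 50.0, "PR": 60.0, "SL": 200.0, "CV": 100.0}[trait], None)
            np.testing.assert_allclose(derived, target, rtol=1e-9)

    def test_twelve_lead_backsolve_floors_at_component_leads(self, bundle):
        b, _ = bundle
        from ecgherit.synthetic_data import _TRAIT_SCALE

        mean, sd = _TRAIT_SCALE["12LS"]
        derived = np.array([derived_trait(r, "12LS") for r in b.records])
        target = mean + sd * b.traits["12LS"].to_numpy()
        # exact wherever the target exceeds the SL/CV-fixed floor
        free = derived > target - 1e-6
        assert free.mean() > 0.95
        np.testing.assert_allclose(derived[np.isclose(derived, target, rtol=1e-9)],
                                   target[np.isclose(derived, target, rtol=1e-9)])

    def test_flagged_individuals_are_dropped(self, bundle):
        b, _ = bundle
        flagged = {r.id for r in b.records if any(r.flags.values())}
        kept, dropped = apply_exclusions(b.records, "QT")
        flag_dropped = {r.id for r, reason in dropped if reason in r.flags and r.flags.get(reason, False)}
        assert flagged <= {r.id for r, _ in dropped}
        assert flag_dropped == flagged

    def test_per_trait_analysis_n_in_study_range(self):
        cfg = SimulationConfig(seed=77)
        b = simulate_ecg_cohort(cfg)
        n = len(b.records)
        for trait in ("QRS", "QT", "PR", "SL", "CV", "12LS"):
            kept, _ = apply_exclusions(b.records, trait)
            assert len(kept) >= 0.94 * n  # mirrors 1396-1474 of 1474 analyzable
            assert len(kept) <= n
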