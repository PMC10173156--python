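import numpy as np
import pytest
from scipy import integrate

from polycore.geno_io import MISSING, ValidationError
from polycore.ploidy import call_ploidy, st_frequencies
from polycore.synthetic_data import (
    SyntheticPanelConfig,
    simulate_panel,
    simulate_phenotypes,
    simulate_reference_panel,
)


def uniform_expectation(fn, lo=0.05, hi=0.95):
    """E[fn(p)] for p ~ Uniform(lo, hi), by numerical integration."""
    val, _ = integrate.quad(lambda p: fn(p) / (hi - lo), lo, hi)
    return val


class TestSimulatePanel:
    def test_seed_determinism(self):
        cfg = SyntheticPanelConfig(
            group_sizes=(10, 10),
            group_ploidy=(2, 4),
            n_markers=100,
            miscall_rate=0.02,
            missing_rate=0.05,
            n_replicate_pairs=2,
            seed=42,
        )
        m1, meta1, t1 = simulate_panel(cfg)
        m2, meta2, t2 = simulate_panel(cfg)
        assert np.array_equal(m1.calls, m2.calls)
        assert m1.sample_ids == m2.sample_ids
        assert t1.labels == t2.labels
        assert [a.__dict__ for a in meta1] == [a.__dict__ for a in meta2]

    def test_clean_diploids_only_even_dosage(self):
        cfg = SyntheticPanelConfig(
            group_sizes=(25,), group_ploidy=(2,), n_markers=400, seed=3
        )
        m, _, _ = simulate_panel(cfg)
        assert set(np.unique(m.calls)) <= {0, 2, 4}
        assert (st_frequencies(m) == 0.0).all()

    def test_triploid_dosage_support(self):
        cfg = SyntheticPanelConfig(
            group_sizes=(20,), group_ploidy=(3,), n_markers=300, seed=4
        )
        m, _, _ = simulate_panel(cfg)
        assert set(np.unique(m.calls)) <= {0, 1, 3, 4}

    def test_tetraploid_st_freq_matches_integral_oracle(self):
        cfg = SyntheticPanelConfig(
            group_sizes=(30,),
            group_ploidy=(4,),
            n_markers=2000,
            divergence=0.0,
            seed=9,
        )
        m, _, _ = simulate_panel(cfg)
        expected = uniform_expectation(
            lambda p: 4 * p * (1 - p) ** 3 + 4 * p**3 * (1 - p)
        )
        st = st_frequencies(m)
        # marker-level frequencies are shared across samples, so the Monte
        # Carlo error is driven by the L simulated markers
        per_marker = ((m.calls == 1) | (m.calls == 3)).mean(axis=0)
        mc_sd = per_marker.std(ddof=1) / np.sqrt(m.n_markers)
        assert abs(st.mean() - expected) < 3 * mc_sd + 1e-3

    def test_diploid_ho_matches_integral_oracle(self):
        cfg = SyntheticPanelConfig(
            group_sizes=(30,),
            group_ploidy=(2,),
            n_markers=2000,
            divergence=0.0,
            seed=10,
        )
        m, _, _ = simulate_panel(cfg)
        from polycore.diversity import observed_heterozygosity

        # diploid heterozygote (dosage 2) has probability 2pq
        expected = uniform_expectation(lambda p: 2 * p * (1 - p))
        ho = observed_heterozygosity(m).ho
        per_marker = (m.calls == 2).mean(axis=0)
        mc_sd = per_marker.std(ddof=1) / np.sqrt(m.n_markers)
        assert abs(ho.mean() - expected) < 3 * mc_sd + 1e-3

    def test_missing_rate(self):
        cfg = SyntheticPanelConfig(
            group_sizes=(20,), group_ploidy=(4,), n_markers=500, missing_rate=0.1, seed=6
        )
        m, _, _ = simulate_panel(cfg)
        assert (m.calls == MISSING).mean() == pytest.approx(0.1, abs=0.01)

    def test_replicates_share_group_and_metadata(self):
        cfg = SyntheticPanelConfig(
            group_sizes=(10, 10),
            group_ploidy=(2, 4),
            n_markers=50,
            n_replicate_pairs=3,
            seed=1,
        )
        m, meta, truth = simulate_panel(cfg)
        assert m.n_samples == 23
        groups = {}
        for mm, lab in zip(meta, truth.labels):
            if mm.replicate_group:
                groups.setdefault(mm.replicate_group, []).append(lab)
        assert len(groups) == 3
        for labs in groups.values():
            assert len(labs) == 2 and labs[0] == labs[1]

    def test_f_zero_uses_ancestral_freqs(self):
        cfg = SyntheticPanelConfig(
            group_sizes=(5, 5), group_ploidy=(4, 4), n_markers=100, divergence=0.0, seed=2
        )
        _, _, truth = simulate_panel(cfg)
        assert np.array_equal(truth.group_freqs[0], truth.group_freqs[1])

    def test_invalid_config(self):
        with pytest.raises(ValidationError):
            SyntheticPanelConfig(group_sizes=(5,), group_ploidy=(2, 4))
        with pytest.raises(ValidationError):
            SyntheticPanelConfig(group_ploidy=(2, 5))
        with pytest.raises(ValidationError):
            SyntheticPanelConfig(miscall_rate=1.5)


class TestReferencePanel:
    def _panel(self):
        cfg = SyntheticPanelConfig(
            group_sizes=(200, 200),
            group_ploidy=(2, 4),
            n_markers=10,
            seed=8,
        )
        m, meta, truth = simulate_panel(cfg)
        return simulate_reference_panel(meta, truth), truth

    def test_chromosome_counts_exact(self):
        ref, truth = self._panel()
        for m, ploidy in zip(ref, truth.ploidies):
            assert m.chromosome_count == 12 * ploidy

    def test_chloroplast_means(self):
        ref, truth = self._panel()
        dips = [m.chloroplast_count for m, p in zip(ref, truth.ploidies) if p == 2]
        tets = [m.chloroplast_count for m, p in zip(ref, truth.ploidies) if p == 4]
        assert np.mean(dips) == pytest.approx(7.6, abs=3 * 0.83 / np.sqrt(len(dips)))
        assert np.mean(tets) == pytest.approx(13.2, abs=3 * 1.06 / np.sqrt(len(tets)))


class TestPhenotypes:
    def _truth(self, seed=0):
        cfg = SyntheticPanelConfig(
            group_sizes=(30, 30, 30), group_ploidy=(2, 4, 4), n_markers=10, seed=seed
        )
        _, _, truth = simulate_panel(cfg)
        return truth

    def test_zero_noise_group_constant(self):
        truth = self._truth()
        pheno = simulate_phenotypes(truth, noise_cv=0.0, seed=1)
        labels = np.asarray(truth.labels)
        for g in range(3):
            sub = pheno.values[labels == g]
            assert (sub == sub[0]).all()

    def test_default_anova_rejects(self):
        from polycore.ploidy import anova_oneway

        truth = self._truth(seed=3)
        pheno = simulate_phenotypes(truth, seed=2)
        labels = np.asarray(truth.labels)
        for t in range(pheno.values.shape[1]):
            groups = [pheno.values[labels == g, t] for g in range(3)]
            _, p = anova_oneway(groups)
            assert p < 0.01

    def test_missing_rate(self):
        truth = self._truth()
        pheno = simulate_phenotypes(truth, missing_rate=0.3, seed=4)
        assert np.isnan(pheno.values).mean() == pytest.approx(0.3, abs=0.05)

    def test_ids_match_panel(self):
        truth = self._truth()
        pheno = simulate_phenotypes(truth, seed=5)
        assert pheno.accession_ids == truth.sample_ids


def test_end_to_end_recovery():
    """Ploidy calls ~match truth and AMOVA is significant on a default panel."""
    from polycore.diversity import amova, mrd_matrix

    cfg = SyntheticPanelConfig(
        group_sizes=(60, 120),
        group_ploidy=(2, 4),
        n_markers=1000,
        divergence=0.25,
        miscall_rate=0.01,
        missing_rate=0.02,
        seed=13,
    )
    matrix, _, truth = simulate_panel(cfg)
    calls = call_ploidy(matrix)
    want = {2: "diploid", 4: "tetraploid"}
    n_match = sum(
        1 for c, p in zip(calls, truth.ploidies) if c.call == want[p]
    )
    assert n_match / len(calls) >= 0.99
    labels = [f"g{k}" for k in truth.labels]
    res = amova(mrd_matrix(matrix), labels, n_perm=99, seed=0)
    assert res.p_value <= 0.01
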