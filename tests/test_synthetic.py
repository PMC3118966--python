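import dataclasses

import numpy as np
import pytest
from scipy import stats

from dmhprep.exceptions import GenerationError
from dmhprep.normalization import compute_ma, fit_loess
from dmhprep.background import correct_background
from dmhprep.restriction import find_recognition_sites, identify_control_probes
from dmhprep.scoring import fit_island_quantile_model
from dmhprep.synthetic import (
    SyntheticConfig,
    dye_bias_curve,
    generate_dataset,
    generate_layout,
    m_noise_sample,
    simulate_dataset,
    simulate_null_island_blocks,
    write_dataset,
)

NULL_CONFIG = SyntheticConfig(
    n_arrays=4,
    n_methylated_islands=5,
    n_housekeeping_islands=5,
    n_other_islands=5,
    n_control_probes=40,
    delta=0.0,
    dye_bias_coeffs=(0.0,),
    dye_affinity_sd=0.0,
)


def normexp_convolution_cdf(x, alpha, mu, sigma):
    """CDF of Exponential(mean alpha) + Normal(mu, sigma^2)."""
    lam = 1.0 / alpha
    u = (x - mu) / sigma
    return stats.norm.cdf(u) - np.exp(
        -lam * (x - mu) + 0.5 * lam**2 * sigma**2
    ) * stats.norm.cdf(u - lam * sigma)


class TestGenerateLayout:
    def test_probe_count_and_exact_control_recovery(self):
        genome, ann, truth = generate_layout(50, 4, 30, 10, seed=7)
        assert len(ann) == 50 * 4 + 30
        found = identify_control_probes(ann, genome)
        assert found.probe_ids == truth.control_probe_ids
        assert len(truth.control_probe_ids) == 30

    def test_every_island_has_promoter_probe(self):
        _, ann, _ = generate_layout(20, 3, 5, 8, seed=1)
        by_island = ann.island_probes().groupby("island_id")["in_promoter"].any()
        assert by_island.all()

    def test_deterministic_for_fixed_seed(self):
        g1, a1, t1 = generate_layout(10, 3, 5, 3, seed=7)
        g2, a2, t2 = generate_layout(10, 3, 5, 3, seed=7)
        assert g1["chrS"] == g2["chrS"]
        assert a1.data.equals(a2.data)
        assert t1.control_probe_ids == t2.control_probe_ids

    def test_seed_changes_layout(self):
        g1, a1, _ = generate_layout(10, 3, 5, 3, seed=7)
        g2, a2, _ = generate_layout(10, 3, 5, 3, seed=8)
        assert g1["chrS"] != g2["chrS"]
        assert not a1.data["probe_id"].equals(a2.data["probe_id"])

    def test_non_control_probes_have_sites_in_window(self):
        genome, ann, truth = generate_layout(12, 3, 6, 4, seed=2)
        seq = genome["chrS"]
        for _, row in ann.data.iterrows():
            center = (row["start"] + row["end"]) // 2
            window = seq[center - 450 : center + 450]
            has_site = bool(find_recognition_sites(window))
            assert has_site != (row["probe_id"] in truth.control_probe_ids)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_islands=0, probes_per_island=4, n_control_probes=5, n_housekeeping_islands=1),
            dict(n_islands=5, probes_per_island=2, n_control_probes=5, n_housekeeping_islands=1),
            dict(n_islands=5, probes_per_island=4, n_control_probes=5, n_housekeeping_islands=7),
            dict(n_islands=5, probes_per_island=4, n_control_probes=5, n_housekeeping_islands=1, spacing=500),
        ],
    )
    def test_infeasible_requests_rejected(self, kwargs):
        with pytest.raises(GenerationError):
            generate_layout(seed=0, **kwargs)


class TestSimulateDataset:
    def test_null_configuration_has_centered_m(self):
        genome, ann, arrays, truth = generate_dataset(NULL_CONFIG, seed=5)
        ms = []
        for arr in arrays:
            ma = compute_ma(correct_background(arr, "subtract"))
            ms.append(ma.M[np.isfinite(ma.M)])
        m = np.concatenate(ms)
        se = m.std(ddof=1) / np.sqrt(m.size)
        assert abs(m.mean()) < 3 * se

    def test_deterministic_and_seed_sensitive(self):
        _, _, a1, t1 = generate_dataset(NULL_CONFIG, seed=5)
        _, _, a2, _ = generate_dataset(NULL_CONFIG, seed=5)
        _, _, a3, _ = generate_dataset(NULL_CONFIG, seed=6)
        assert a1[0].data.equals(a2[0].data)
        assert not a1[0].data.equals(a3[0].data)

    def test_background_subtracted_green_matches_normexp_convolution(self):
        """KS check of the intensity core against the convolution CDF."""
        cfg = dataclasses.replace(NULL_CONFIG, n_other_islands=40)
        _, _, arrays, truth = generate_dataset(cfg, seed=9)
        p = truth.normexp_truth["G"]
        rejected = 0
        for arr in arrays:
            x = (arr.data["Gf"] - arr.data["Gb"]).to_numpy()
            stat = stats.kstest(
                x, lambda q: normexp_convolution_cdf(q, p["alpha"], p["mu"], p["sigma"])
            )
            rejected += stat.pvalue < 0.01
        assert rejected <= 1

    def test_methylated_islands_show_elevated_m(self):
        cfg = dataclasses.replace(NULL_CONFIG, delta=2.0, n_arrays=6)
        _, ann, arrays, truth = generate_dataset(cfg, seed=3)
        island = truth.methylated_island_ids[0]
        pos_arrays = truth.methylation_indicators.loc[island]
        probe_sel = (ann.data["island_id"] == island).to_numpy()
        ctrl_sel = np.fromiter(
            (p in truth.control_probe_ids for p in ann.data["probe_id"]), bool, len(ann.data)
        )
        for arr in arrays:
            ma = compute_ma(correct_background(arr, "subtract"))
            diff = np.nanmedian(ma.M[probe_sel]) - np.nanmedian(ma.M[ctrl_sel])
            if pos_arrays[arr.array_id]:
                assert diff > 1.0
            else:
                assert abs(diff) < 1.0

    def test_injected_dye_bias_recovered_by_global_loess(self):
        cfg = dataclasses.replace(
            NULL_CONFIG,
            n_arrays=2,
            n_other_islands=330,  # ~2000 biological probes
            dye_bias_coeffs=(0.4, -0.1, 0.02),
        )
        _, _, arrays, truth = generate_dataset(cfg, seed=13)
        # foreground-only correction keeps observed A identical to the A
        # the bias curve was applied at
        ma = compute_ma(correct_background(arrays[0], "none"))
        ok = np.isfinite(ma.M)
        curve = fit_loess(ma.A[ok], ma.M[ok], span=0.3)
        lo, hi = np.quantile(ma.A[ok], [0.1, 0.9])
        grid = np.linspace(lo, hi, 100)
        planted = dye_bias_curve(grid, truth.dye_bias_coeffs, truth.dye_bias_ref)
        assert np.max(np.abs(curve(grid) - planted)) < 0.05

    def test_strong_effect_yields_high_scores(self):
        """A two-fold-plus effect present in most arrays drives the island
        score close to the number of positive arrays."""
        hits = 0
        for seed in range(10):
            cfg = dataclasses.replace(
                NULL_CONFIG, delta=2.0, n_arrays=26, prevalence=20 / 26,
                n_methylated_islands=2,
            )
            _, ann, arrays, truth = generate_dataset(cfg, seed=100 + seed)
            island = truth.methylated_island_ids[0]
            n_pos = int(truth.methylation_indicators.loc[island].sum())
            m = {}
            for arr in arrays:
                ma = compute_ma(correct_background(arr, "subtract"))
                sel = (ann.data["island_id"] == island).to_numpy()
                m[arr.array_id] = ma.M[sel]
            import pandas as pd

            block = pd.DataFrame(m, index=[f"p{i}" for i in range(cfg.probes_per_island)])
            fit = fit_island_quantile_model(block)
            score = int(np.sum(fit.p_values < 0.05))
            if score >= min(15, n_pos):
                hits += 1
        assert hits >= 9

    def test_invalid_parameters_rejected(self):
        genome, ann, truth = generate_layout(5, 3, 5, 1, seed=0)
        with pytest.raises(GenerationError):
            simulate_dataset(ann, truth, n_arrays=1, seed=0)
        with pytest.raises(GenerationError):
            simulate_dataset(
                ann, truth, n_arrays=4, seed=0,
                config=dataclasses.replace(NULL_CONFIG, delta=-1.0),
            )


class TestNullIslandBlocks:
    def test_blocks_satisfy_model_null(self):
        blocks = simulate_null_island_blocks(5, 6, 8, seed=3, pool_size=200_000)
        assert len(blocks) == 5
        assert blocks[0].shape == (6, 8)
        pooled = np.concatenate([b.to_numpy().ravel() for b in blocks])
        # noise recentred at its 75th percentile: about 25% of mass above 0
        frac_above = (pooled > 0).mean()
        assert abs(frac_above - 0.25) < 0.05

    def test_noise_pool_deterministic(self):
        a = m_noise_sample(10_000, seed=4)
        b = m_noise_sample(10_000, seed=4)
        np.testing.assert_array_equal(a, b)


def test_write_dataset_round_trips(tmp_path, small_dataset):
    from dmhprep.io import read_feature_tables, read_genome_fasta, read_probe_annotation

    write_dataset(
        small_dataset["genome"],
        small_dataset["annotation"],
        small_dataset["arrays"][:2],
        small_dataset["truth"],
        tmp_path,
    )
    genome = read_genome_fasta(tmp_path / "genome.fa")
    assert genome["chrS"] == small_dataset["genome"]["chrS"]
    ann = read_probe_annotation(tmp_path / "probes.bed")
    assert ann.data["probe_id"].equals(small_dataset["annotation"].data["probe_id"])
    arrays = read_feature_tables(sorted(tmp_path.glob("array_*.tsv")))
    assert arrays[0].array_id == "array_01"
    np.testing.assert_allclose(
        arrays[0].data["Rf"], small_dataset["arrays"][0].data["Rf"], atol=1e-3
    )
    assert (tmp_path / "truth.json").exists()
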