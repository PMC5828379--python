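"""Synthetic cells, measurement model, dataset and cohort generation."""

import json

import numpy as np
import pytest

from navclamp.gating import load_params
from navclamp.io import read_sweeps
from navclamp.protocols import make_recovery, make_step_iv, simulate
from navclamp.synth import (
    CohortSpec,
    DatasetConfig,
    NoiseConfig,
    corrupt,
    default_spread,
    generate_cohort,
    generate_dataset,
    sample_cell,
)
from navclamp.variants import count_carriers


class TestSampleCell:
    def test_zero_spread_copies_group_means(self):
        wt = load_params("WT")
        cell = sample_cell(wt, {k: 0.0 for k in default_spread("WT")}, rng_seed=7)
        assert cell.params == wt.replace()  # identical field values
        assert cell.group == "WT"

    def test_deterministic_given_seed(self):
        wt = load_params("WT")
        spread = default_spread("WT")
        c1 = sample_cell(wt, spread, rng_seed=42)
        c2 = sample_cell(wt, spread, rng_seed=42)
        assert c1.params == c2.params
        c3 = sample_cell(wt, spread, rng_seed=43)
        assert c3.params != c1.params

    def test_monte_carlo_spread_matches_sem_rule(self):
        # cell-level SD of fast-inactivation V1/2 = SEM * sqrt(n) = 1.4*sqrt(18)
        wt = load_params("WT")
        target_sd = 1.4 * np.sqrt(18)
        spread = {"fast_v_half": target_sd}
        draws = np.array(
            [sample_cell(wt, spread, rng_seed=s).params.fast_v_half for s in range(1000)]
        )
        assert np.std(draws, ddof=1) == pytest.approx(target_sd, rel=0.10)

    def test_invariants_enforced_by_resampling(self):
        wt = load_params("WT")
        # huge spread on a positivity-constrained field: every draw valid
        for s in range(50):
            cell = sample_cell(wt, {"act_k": 50.0, "tau_h_hyper": 80.0}, rng_seed=s)
            assert cell.params.act_k > 0
            assert cell.params.tau_h_depol < cell.params.tau_h_hyper


class TestCorrupt:
    def test_zero_noise_is_identity(self):
        wt = load_params("WT")
        ss = simulate(make_step_iv(), wt)
        quiet = corrupt(ss, NoiseConfig(current_noise_sd=0.0, leak_conductance=0.0,
                                        enable_p5=False, filter_window=1), rng_seed=0)
        for a, b in zip(ss.sweeps, quiet.sweeps):
            assert np.array_equal(a.current_pa, b.current_pa)

    def test_noise_sd_by_construction(self):
        wt = load_params("WT")
        ss = simulate(make_step_iv(), wt)
        sd = 10.0
        noisy = corrupt(ss, NoiseConfig(current_noise_sd=sd, leak_conductance=0.0,
                                        enable_p5=False, filter_window=1), rng_seed=1)
        resid = np.concatenate(
            [n.current_pa - c.current_pa for n, c in zip(noisy.sweeps, ss.sweeps)]
        )
        assert np.std(resid) == pytest.approx(sd, rel=0.10)

    def test_p5_cancels_leak_in_expectation(self):
        # recovery protocol: long interpulse at -100 mV with ~zero channel
        # current; after P/5 correction the mean residual there must vanish
        wt = load_params("WT")
        proto = make_recovery()
        ss = simulate(proto, wt)
        sd, g_leak = 10.0, 2.0
        cfg = NoiseConfig(current_noise_sd=sd, leak_conductance=g_leak, enable_p5=True)
        corrected = corrupt(ss, cfg, rng_seed=3)
        sw = corrected.sweeps[-1]  # longest interpulse
        i0, i1 = corrected.segment_bounds(sw.index)[1]
        lo = i0 + (i1 - i0) // 2  # second half: fast gate largely recovered
        resid = sw.current_pa[lo:i1] - ss.sweeps[-1].current_pa[lo:i1]
        n = i1 - lo
        # corrected trace sums 6 noisy traces -> mean residual SD = sd*sqrt(6/n)
        assert abs(np.mean(resid)) < 4.0 * sd * np.sqrt(6.0 / n)
        # without correction the leak at -100 mV is -200 pA, far outside that bound
        assert abs(g_leak * -100.0) > 10 * sd * np.sqrt(6.0 / n)

    def test_filter_reduces_noise_variance(self):
        wt = load_params("WT")
        ss = simulate(make_step_iv(), wt)
        cfg = NoiseConfig(current_noise_sd=10.0, enable_p5=False, filter_window=4)
        smoothed = corrupt(ss, cfg, rng_seed=5)
        resid = smoothed.sweeps[0].current_pa - ss.sweeps[0].current_pa
        # moving average over w samples shrinks white-noise SD by ~sqrt(w)
        assert np.std(resid) == pytest.approx(10.0 / 2.0, rel=0.2)


SMALL_CONFIG = DatasetConfig(
    group_sizes={"WT": 2, "M1852T": 1, "T1596I": 1},
    protocols=("step_iv",),
)


class TestGenerateDataset:
    def test_layout_and_manifest(self, tmp_path):
        manifest = generate_dataset(SMALL_CONFIG, tmp_path, master_seed=11)
        assert len(manifest["cells"]) == 4
        groups = [c["group"] for c in manifest["cells"]]
        assert groups.count("WT") == 2
        on_disk = json.loads((tmp_path / "manifest.json").read_text())
        assert on_disk["master_seed"] == 11
        for cell in manifest["cells"]:
            assert (tmp_path / "cells" / cell["cell_id"] / "step_iv.csv").exists()
            assert 0 <= cell["seed"] < 2**31

    def test_byte_identical_regeneration(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_dataset(SMALL_CONFIG, d1, master_seed=5)
        generate_dataset(SMALL_CONFIG, d2, master_seed=5)
        files1 = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        files2 = sorted(p.relative_to(d2) for p in d2.rglob("*") if p.is_file())
        assert files1 == files2
        for rel in files1:
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes()

    def test_zero_noise_reproduces_simulate(self, tmp_path):
        config = DatasetConfig(
            group_sizes={"WT": 1}, protocols=("step_iv",), noise=None,
            spreads={"WT": {}},
        )
        generate_dataset(config, tmp_path, master_seed=0)
        ss = read_sweeps(tmp_path / "cells" / "WT_000" / "step_iv.csv")
        ref = simulate(make_step_iv(), load_params("WT"))
        for a, b in zip(ss.sweeps, ref.sweeps):
            assert np.array_equal(a.current_pa, b.current_pa)


class TestGenerateCohort:
    def test_study_structure(self):
        variants, participants = generate_cohort(CohortSpec(), rng_seed=0)
        assert len(variants) == 12
        assert (participants["group"] == "painful").sum() == 111
        assert (participants["group"] == "painless").sum() == 78
        carriers = set()
        for ids in variants["carrier_ids"]:
            carriers.update(x for x in ids.split(",") if x)
        assert len(carriers) == 10
        painful = set(participants.loc[participants.group == "painful", "participant_id"])
        assert carriers <= painful
        # one carrier holds four variants; one variant is shared by two carriers
        per_carrier = {c: 0 for c in carriers}
        for ids in variants["carrier_ids"]:
            for c in filter(None, ids.split(",")):
                per_carrier[c] += 1
        assert max(per_carrier.values()) == 4
        assert max(len(ids.split(",")) for ids in variants["carrier_ids"]) == 2

    def test_counts_feed_carrier_table(self):
        from navclamp.variants import _records_from_frame

        variants, participants = generate_cohort(CohortSpec(), rng_seed=1)
        records = _records_from_frame(variants)
        assignments = dict(zip(participants["participant_id"], participants["group"]))
        table = count_carriers(records, assignments)
        assert (table.a, table.b, table.c, table.d) == (10, 101, 0, 78)

    def test_zero_carriers(self):
        spec = CohortSpec(n_painful=20, n_painless=15, n_variants=3, n_carriers=0)
        variants, participants = generate_cohort(spec, rng_seed=2)
        assert all(ids == "" for ids in variants["carrier_ids"])

    def test_deterministic(self):
        v1, p1 = generate_cohort(CohortSpec(), rng_seed=9)
        v2, p2 = generate_cohort(CohortSpec(), rng_seed=9)
        assert v1.equals(v2) and p1.equals(p2)
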