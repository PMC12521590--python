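import math

import numpy as np
import pytest
from scipy import stats

from terminome_miner.io_formats import PipelineConfig
from terminome_miner.synthetic_data import (ProteaseSpec, SimulationConfig,
                                            SpecificityModel,
                                            default_proteases,
                                            generate_proteome, make_design,
                                            plant_cleavages, simulate_cohort,
                                            write_simulation)
from terminome_miner.terminome import call_termini

from conftest import quiet_config


def binom_ci(n, p, conf=0.99):
    return stats.binom.interval(conf, n, p)


class TestSpecificityModel:
    def test_probabilities_sum_to_one_per_position(self):
        m = SpecificityModel.with_preferences("X", {"P1'": {"A": 0.8}})
        for pos in m.log_odds:
            assert m.residue_probs(pos).sum() == pytest.approx(1.0)

    def test_target_probability_reproduced(self):
        m = SpecificityModel.with_preferences("X", {"P1'": {"A": 0.8}})
        probs = dict(zip("ACDEFGHIKLMNPQRSTVWY", m.residue_probs("P1'")))
        assert probs["A"] == pytest.approx(0.8)

    def test_zero_temperature_degenerate(self):
        m = SpecificityModel.with_preferences("X", {"P1'": {"A": 0.8}},
                                              temperature=0.0)
        probs = m.residue_probs("P1'")
        assert probs.max() == 1.0 and probs.sum() == 1.0


class TestGenerateProteome:
    def test_seed_determinism_byte_identical_fasta(self, tmp_path):
        cfg = SimulationConfig(seed=1, n_proteins=5)
        for run in ("a", "b"):
            write_simulation(simulate_cohort(cfg), tmp_path / run)
        assert (tmp_path / "a" / "proteome.fasta").read_bytes() == \
               (tmp_path / "b" / "proteome.fasta").read_bytes()

    def test_signal_fraction_one_annotates_all(self):
        cfg = SimulationConfig(seed=2, n_proteins=10, signal_fraction=1.0)
        records, signal_ends = generate_proteome(cfg)
        assert all(r.signal_end is not None for r in records)
        assert len(signal_ends) == 10

    def test_signal_fraction_within_binomial_ci(self):
        cfg = SimulationConfig(seed=3, n_proteins=500, signal_fraction=0.4)
        records, signal_ends = generate_proteome(cfg)
        lo, hi = binom_ci(500, 0.4)
        assert lo <= len(signal_ends) <= hi

    def test_degenerate_length_distribution_error(self):
        with pytest.raises(ValueError, match="length"):
            SimulationConfig(seed=1, length_range=(300, 100))

    def test_requested_count_and_signal_range(self):
        cfg = SimulationConfig(seed=4, n_proteins=50, signal_fraction=1.0)
        records, signal_ends = generate_proteome(cfg)
        assert len(records) == 50
        assert all(15 <= e <= 30 for e in signal_ends.values())


class TestPlantCleavages:
    def test_degenerate_specificity_forces_p1_prime(self):
        forced = SpecificityModel.with_preferences("F", {"P1'": {"A": 0.999}},
                                                   temperature=0.0)
        cfg = SimulationConfig(
            seed=5, n_proteins=30,
            proteases=[ProteaseSpec(forced, 0.05, {"CASE": 1.0, "CTRL": 1.0})])
        proteome, _ = generate_proteome(cfg)
        truths = plant_cleavages(proteome, cfg)
        by_acc = {p.accession: p for p in proteome}
        assert truths
        for t in truths:
            assert by_acc[t.accession].sequence[t.p1_position] == "A"

    def test_group_exclusive_sites_attributed_to_their_protease(self):
        cfg = quiet_config(seed=6)
        proteome, _ = generate_proteome(cfg)
        truths = plant_cleavages(proteome, cfg)
        spec_b = cfg.proteases[1]
        cfg2 = SimulationConfig(
            seed=6, n_proteins=20,
            proteases=[cfg.proteases[0],
                       ProteaseSpec(spec_b.model, spec_b.site_rate,
                                    {"CASE": 0.7, "CTRL": 0.0})],
            decoy_rate=0.0)
        truths2 = plant_cleavages(proteome, cfg2)
        ctrl_zero = [t for t in truths2 if t.occurrence["CTRL"] == 0.0]
        assert ctrl_zero and all(t.protease == spec_b.name for t in ctrl_zero)

    def test_uniform_model_acceptance_within_binomial_ci(self):
        uniform = SpecificityModel.uniform("U")
        rate = 0.1
        cfg = SimulationConfig(
            seed=7, n_proteins=60, signal_fraction=0.0,
            proteases=[ProteaseSpec(uniform, rate, {"CASE": 1.0, "CTRL": 1.0})])
        proteome, _ = generate_proteome(cfg)
        n_eligible = sum(
            sum(1 for p1 in range(cfg.site_margin, len(pr) - cfg.site_margin + 1)
                if pr.sequence[p1 - 1] not in "KR")
            for pr in proteome)
        truths = plant_cleavages(proteome, cfg)
        lo, hi = binom_ci(n_eligible, rate)
        assert lo <= len(truths) <= hi

    def test_sites_never_at_protein_ends(self):
        cfg = quiet_config(seed=8)
        proteome, _ = generate_proteome(cfg)
        by_acc = {p.accession: p for p in proteome}
        for t in plant_cleavages(proteome, cfg):
            assert 0 < t.p1_position < len(by_acc[t.accession])

    def test_no_protease_error(self):
        cfg = quiet_config(seed=9)
        cfg.proteases = []
        proteome, _ = generate_proteome(cfg)
        with pytest.raises(ValueError):
            plant_cleavages(proteome, cfg)


class TestSimulatedReport:
    def test_decoy_free_semi_boundaries_all_truth(self):
        res = simulate_cohort(quiet_config(seed=10))
        semi = res.row_sidecar[res.row_sidecar["provenance"] != "tryptic"]
        truth_p1 = {(t.accession, t.p1_position) for t in res.truths}
        assert len(semi) > 0
        assert all((r.accession, r.p1_position) in truth_p1
                   for r in semi.itertuples())

    def test_every_row_has_exactly_one_provenance(self):
        res = simulate_cohort(SimulationConfig(seed=11, n_proteins=20))
        assert len(res.row_sidecar) == len(res.rows)
        assert set(res.row_sidecar["row_id"]) == set(range(len(res.rows)))
        assert res.row_sidecar["provenance"].str.match(
            r"^(tryptic|decoy|truth:.+)$").all()

    def test_flat_missingness_within_binomial_ci(self):
        p_miss = 0.2
        cfg = quiet_config(seed=12, n_proteins=40,
                           missing_intercept=float(np.log(p_miss / (1 - p_miss))),
                           missing_slope=0.0)
        res = simulate_cohort(cfg)
        tryptic_ids = set(
            res.row_sidecar.loc[res.row_sidecar["provenance"] == "tryptic", "row_id"])
        cells = [v for i in tryptic_ids
                 for v in res.rows[i].intensities.values()]
        n_missing = sum(1 for v in cells if math.isnan(v))
        lo, hi = binom_ci(len(cells), p_miss)
        assert lo <= n_missing <= hi

    def test_group_effect_recovered_across_replicates(self):
        """Monte-Carlo oracle: planted log2 effect of -2 on the depleted
        protease's termini recovered within 3 SEM over 50 replicate cohorts."""
        diffs = []
        for seed in range(50):
            cfg = quiet_config(seed=1000 + seed, n_proteins=4,
                               length_range=(150, 250))
            res = simulate_cohort(cfg)
            target = res.row_sidecar["provenance"] == "truth:CTRLPROT_SYN"
            case = [s for s in res.design.samples if s.startswith("CASE")]
            ctrl = [s for s in res.design.samples if s.startswith("CTRL")]
            for i in res.row_sidecar.loc[target, "row_id"]:
                vals = res.rows[i].intensities
                d = (np.mean([np.log2(vals[s]) for s in case])
                     - np.mean([np.log2(vals[s]) for s in ctrl]))
                diffs.append(d)
        diffs = np.asarray(diffs)
        sem = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean() - (-2.0)) <= 3 * sem

    def test_perfect_recovery_limit(self, config):
        """Decoys off, missingness off, full occurrence: the called neo-N P1
        set equals the planted (emitted) truth set exactly."""
        res = simulate_cohort(quiet_config(seed=13, n_proteins=30))
        proteome = {p.accession: p for p in res.proteome}
        n_events, _, _ = call_termini(res.rows, proteome, res.design, config)
        st = res.site_table
        truth = set(zip(st[st.emitted_neoN].accession,
                        st[st.emitted_neoN].p1_position))
        called = {(e.accession, e.p1_position) for e in n_events
                  if e.category == "neo"}
        assert called == truth

    def test_false_discovery_proportion_tracks_decoy_fraction(self, config):
        """With decoys on, the FDP of called neo termini equals the decoy
        share of distinct semi-tryptic boundaries in the sidecar."""
        cfg = quiet_config(seed=14, n_proteins=60, decoy_rate=0.05,
                           decoy_presence=1.0)
        res = simulate_cohort(cfg)
        proteome = {p.accession: p for p in res.proteome}
        n_events, _, _ = call_termini(res.rows, proteome, res.design, config)
        called = {(e.accession, e.p1_position) for e in n_events
                  if e.category == "neo"}
        sc = res.row_sidecar
        decoy_sites = set(map(tuple, sc.loc[sc.provenance == "decoy",
                                            ["accession", "p1_position"]].values))
        fdp = len(called & decoy_sites) / len(called)
        neo_truth = set(zip(res.site_table[res.site_table.emitted_neoN].accession,
                            res.site_table[res.site_table.emitted_neoN].p1_position))
        expected = len(decoy_sites) / (len(decoy_sites) + len(neo_truth))
        assert fdp == pytest.approx(expected, abs=0.02)

    def test_same_config_same_outputs(self):
        cfg = SimulationConfig(seed=15, n_proteins=10)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        assert a.row_sidecar.equals(b.row_sidecar)
        assert [r.intensities for r in a.rows] == [r.intensities for r in b.rows]
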