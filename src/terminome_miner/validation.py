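"""Validation experiments: oracle agreement, null error rates and
planted-degradome recovery.

These functions re-derive, at run time, the quantities that certify the
pipeline: agreement of the digestion engine with a brute-force enumeration,
agreement of the moderated test and multiple-testing machinery with
independent formulations, type-I error calibration on null cohorts, and
recovery of planted cleavage sites, protease attributions and positional
preferences from the synthetic degradome.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .cleavage_profile import build_pfm, protease_enrichment, windows_for_events
from .diffstats import bh_adjust, differential_analysis, moderated_t, ora, storey_q
from .digestion import digest_protein
from .io_formats import AMINO_ACIDS, CleavageSiteRecord, PipelineConfig
from .synthetic_data import (ProteaseSpec, SimulationConfig, default_proteases,
                             make_design, simulate_cohort)
from .terminome import exclusivity_label, call_termini, presence_filter


# ---------------------------------------------------------------------------
# digestion oracle
# ---------------------------------------------------------------------------

def brute_force_digest(seq: str, mc: int, proline_rule: bool = True
                       ) -> set[tuple[int, int]]:
    """Enumerate every substring; keep those whose boundaries sit on
    cleavage-rule cut points with at most ``mc`` internal cut points."""

    def is_cut(pos: int) -> bool:
        if pos in (0, len(seq)):
            return True
        return seq[pos - 1] in "KR" and not (proline_rule and seq[pos] == "P")

    out = set()
    for start in range(1, len(seq) + 1):
        for end in range(start, len(seq) + 1):
            if is_cut(start - 1) and is_cut(end):
                if sum(1 for p in range(start, end) if is_cut(p)) <= mc:
                    out.add((start, end))
    return out


def digestion_agreement(n_proteins: int = 200, max_length: int = 60,
                        seed: int = 0) -> float:
    """Fraction of random proteins where the digestion engine equals the
    brute-force oracle for every mc in 0..2 and both proline conventions."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_proteins):
        seq = "".join(AMINO_ACIDS[i]
                      for i in rng.integers(0, 20, rng.integers(5, max_length + 1)))
        ok = all(
            {(p.start, p.end) for p in digest_protein(seq, mc, proline_rule=pr)}
            == brute_force_digest(seq, mc, pr)
            for mc in (0, 1, 2) for pr in (True, False))
        agree += ok
    return agree / n_proteins


# ---------------------------------------------------------------------------
# statistics oracles
# ---------------------------------------------------------------------------

def statistics_oracle_deviations(seed: int = 0) -> dict[str, float]:
    """Maximum deviations of the statistical machinery from independent
    formulations (ordinary t, BH, the defining q-value minimum, exhaustive
    hypergeometric enumeration and exact tail sums)."""
    rng = np.random.default_rng(seed)
    design = make_design(4)
    out: dict[str, float] = {}

    m = pd.DataFrame(rng.normal(20, 2, (100, 8)), columns=design.samples)
    res = moderated_t(m, design, prior_df=0)
    t_ref, _ = stats.ttest_ind(m.iloc[:, :4], m.iloc[:, 4:], axis=1)
    out["moderated_t_vs_pooled_max_dev"] = float(np.abs(res["t_mod"] - t_ref).max())

    p = rng.uniform(size=500)
    out["storey_vs_bh_max_dev"] = float(
        np.abs(storey_q(p, pi0=1.0) - bh_adjust(p)).max())
    q = storey_q(p, lam=0.5)
    order = np.argsort(p)
    mlen = len(p)
    pi0 = min(1.0, float(np.mean(p > 0.5)) / 0.5)
    direct = np.minimum.accumulate(
        (pi0 * mlen * p[order] / np.arange(1, mlen + 1))[::-1])[::-1]
    out["storey_vs_direct_max_dev"] = float(
        np.abs(q[order] - np.clip(direct, 0, 1)).max())

    universe = set("ABCDEFGHIJ")
    hits = set("ABCDE")
    terms = {"T1": set("ABC"), "T2": set("AFGH"), "T3": set("BCDIJ"),
             "T4": set("ABCDE")}
    table = ora(hits, universe, terms).set_index("term")
    draws = list(combinations(sorted(universe), 5))
    dev = 0.0
    for name, members in terms.items():
        k_obs = len(members & hits)
        exact = sum(1 for d in draws if len(members & set(d)) >= k_obs) / len(draws)
        dev = max(dev, abs(table.loc[name, "p"] - exact))
    out["ora_vs_enumeration_max_dev"] = float(dev)

    dev = 0.0
    for _ in range(25):
        N = int(rng.integers(5, 31))
        n = int(rng.integers(1, N))
        K = int(rng.integers(1, N + 1))
        k = int(stats.hypergeom.rvs(N, K, n, random_state=rng))
        p_pkg = float(stats.hypergeom.sf(k - 1, N, K, n))
        tail = float(sum(
            Fraction(math.comb(K, j) * math.comb(N - K, n - j), math.comb(N, n))
            for j in range(k, min(K, n) + 1)))
        dev = max(dev, abs(p_pkg - tail))
    out["fisher_vs_tail_sum_max_dev"] = float(dev)
    return out


# ---------------------------------------------------------------------------
# null calibration
# ---------------------------------------------------------------------------

def null_error_rates(n_features: int = 2000, n_per_group: int = 8,
                     n_reps: int = 100, seed: int = 0) -> dict[str, float]:
    """Type-I error of the moderated test and empirical FDR of q-mode calls
    on cohorts with no group effect."""
    rng = np.random.default_rng(seed)
    design = make_design(n_per_group)
    config = PipelineConfig()
    p05, fdps = [], []
    for _ in range(n_reps):
        m = pd.DataFrame(
            rng.normal(20, 2, n_features)[:, None]
            + rng.normal(0, 1, (n_features, 2 * n_per_group)),
            columns=design.samples)
        res = differential_analysis(m, design, config, mode="protein")
        p05.append(float((res["p_mod"] <= 0.05).mean()))
        n_called = int((res["status"] != "ns").sum())
        fdps.append(n_called / max(n_called, 1))  # all calls are false here
    return {"null_p05_fraction": float(np.mean(p05)),
            "null_empirical_fdr": float(np.mean(fdps))}


# ---------------------------------------------------------------------------
# planted-degradome recovery
# ---------------------------------------------------------------------------

def neo_recovery(seed: int, n_proteins: int = 100) -> dict[str, float]:
    """Recall/precision of called neo-N P1 sites against the planted truth
    under the default study conditions (decoys and missingness on)."""
    sim = simulate_cohort(SimulationConfig(seed=seed, n_proteins=n_proteins))
    proteome = {p.accession: p for p in sim.proteome}
    config = PipelineConfig()
    n_events, _, _ = call_termini(sim.rows, proteome, sim.design, config)
    st = sim.site_table
    truth = set(zip(st[st.emitted_neoN].accession, st[st.emitted_neoN].p1_position))
    called = {(e.accession, e.p1_position) for e in n_events if e.category == "neo"}
    tp = len(truth & called)
    return {"neo_n_recall": tp / len(truth) if truth else float("nan"),
            "neo_n_precision": tp / len(called) if called else float("nan"),
            "n_truth_sites": len(truth), "n_called_sites": len(called)}


def _roster(case_exclusive: bool) -> list[ProteaseSpec]:
    specs = default_proteases()
    if not case_exclusive:  # null: the focal protease is equally active
        focal = specs[1]
        specs[1] = ProteaseSpec(focal.model, focal.site_rate,
                                {"CASE": 0.7, "CTRL": 0.7}, focal.log2_effect)
    return specs


def _case_protease_significant(seed: int, case_exclusive: bool,
                               n_proteins: int, alpha_q: float) -> bool:
    sim = simulate_cohort(SimulationConfig(
        seed=seed, n_proteins=n_proteins, proteases=_roster(case_exclusive)))
    proteome = {p.accession: p for p in sim.proteome}
    config = PipelineConfig()
    n_events, _, _ = call_termini(sim.rows, proteome, sim.design, config)
    kept = presence_filter([e for e in n_events if e.category == "neo"],
                           sim.design, config.min_presence)
    case = sim.design.groups[0]
    fore = [e for e in kept
            if exclusivity_label(e, sim.design, config.exclusivity_fraction)
            == f"exclusive_{case}"]
    if not fore:
        return False
    db = [CleavageSiteRecord(r.accession, int(r.p1_position), r.protease)
          for r in sim.site_table.itertuples()]
    results = protease_enrichment(fore, kept, db)
    focal = [r for r in results if r.protease == "CASEPROT_SYN"]
    return bool(focal) and focal[0].q <= alpha_q


def protease_recovery_rate(n_seeds: int = 50, seed0: int = 0,
                           case_exclusive: bool = True,
                           n_proteins: int = 60,
                           alpha_q: float = 0.05) -> float:
    """Fraction of seeded cohorts where the focal protease reaches q <= alpha
    in the case-exclusive enrichment (power when it is exclusive, false-call
    rate when its activity is identical in both groups)."""
    hits = sum(
        _case_protease_significant(seed0 + i, case_exclusive, n_proteins, alpha_q)
        for i in range(n_seeds))
    return hits / n_seeds


def pfm_preference_recovery(seed: int, n_proteins: int = 100) -> dict[str, float]:
    """Recovered P1' frequency of the case protease's preferred residue
    (planted at 0.8) over that protease's called cleavage windows."""
    sim = simulate_cohort(SimulationConfig(seed=seed, n_proteins=n_proteins))
    proteome = {p.accession: p for p in sim.proteome}
    n_events, _, _ = call_termini(sim.rows, proteome, sim.design, PipelineConfig())
    st = sim.site_table
    focal_sites = set(zip(st[st.protease == "CASEPROT_SYN"].accession,
                          st[st.protease == "CASEPROT_SYN"].p1_position))
    focal_events = [e for e in n_events if e.category == "neo"
                    and (e.accession, e.p1_position) in focal_sites]
    windows = windows_for_events(focal_events, proteome)
    pfm = build_pfm(windows)
    return {"p1_prime_frequency": float(pfm.frequencies.loc["P1'", "A"]),
            "n_windows": pfm.n_windows,
            "planted_frequency": 0.8}


def binomial_interval(n: int, p: float, conf: float = 0.99) -> tuple[float, float]:
    lo, hi = stats.binom.interval(conf, n, p)
    return lo / n, hi / n
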