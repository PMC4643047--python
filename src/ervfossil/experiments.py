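"""Reproducible end-to-end experiments on synthetic ground truth.

Each function runs one pipeline stage at publication scale against the
simulator's planted truth and returns the measured quantities.  They are
what ``scripts/acceptance.py`` and the acceptance-level tests execute;
problem sizes default to the scales described in docs/methods.md.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sp_stats

from . import dating, orthology
from .annotate import pair_ltrs
from .conversion import quartet_topology
from .dating import age_from_divergence, ltr_divergence
from .orthology import GenomeIndex, call_orthology
from .selection import (omega_neutrality_test, pair_codon_stats,
                        poisson_ci, shared_breakpoints, _omega_from_sums)
from .simulate import (InsertionEvent, SimConfig, simulate,
                       simulate_codon_alignment,
                       simulate_env_deletion_family, simulate_ltr_pair,
                       simulate_quartet)


def annotation_recovery(seed: int = 0, n_proviruses: int = 50,
                        n_solo: int = 200) -> dict:
    """Plant proviruses and solo LTRs, annotate the emitted hit table,
    and score recovery against truth."""
    events = tuple(
        [InsertionEvent(5e5, lineage="A", kind="provirus")] * n_proviruses
        + [InsertionEvent(5e5, lineage="A", kind="solo_ltr")] * n_solo)
    n = len(events)
    cfg = SimConfig(seed=seed, genome_len=20_000 * n + 100_000,
                    split_time_years=1e6, insertion_events=events)
    res = simulate(cfg)
    ltr_hits = [h for h in res.rm_out_a if h.family_id.endswith("-LTR")]
    called = pair_ltrs(ltr_hits)
    want_pro = {(l.extent.start, l.extent.end) for l in res.loci_a
                if l.kind == "provirus"}
    want_solo = {(l.extent.start, l.extent.end) for l in res.loci_a
                 if l.kind == "solo_ltr"}
    got_pro = {(l.extent.start, l.extent.end) for l in called
               if l.kind == "provirus"}
    got_solo = {(l.extent.start, l.extent.end) for l in called
                if l.kind == "solo_ltr"}
    recovered = len(want_pro & got_pro) + len(want_solo & got_solo)
    return {
        "n_true_proviruses": len(want_pro),
        "n_true_solo": len(want_solo),
        "recovered_pct": 100.0 * recovered / (len(want_pro)
                                              + len(want_solo)),
        "false_proviruses": len(got_pro - want_pro),
    }


def _max_pairing_bruteforce(hits) -> int:
    from .annotate import _eligible_gap

    def best(avail):
        if not avail:
            return 0
        first, rest = avail[0], avail[1:]
        top = best(rest)
        for j in rest:
            if _eligible_gap(hits[first], hits[j]) is not None:
                top = max(top, 1 + best([k for k in rest if k != j]))
        return top

    return best(list(range(len(hits))))


def pairing_oracle_agreement(seed: int = 0,
                             n_instances: int = 1000) -> dict:
    """Exact matching vs exhaustive enumeration on random small
    instances (<= 8 LTR hits on one contig)."""
    from .core_io import Interval, RepeatHit

    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_instances):
        n = int(rng.integers(0, 9))
        hits = []
        for _ in range(n):
            start = int(rng.integers(0, 40000))
            length = int(rng.integers(500, 700))
            strand = "+" if rng.random() < 0.8 else "-"
            hits.append(RepeatHit(
                2000.0, Interval("c1", start, start + length, strand),
                "LTR1", 1, length, 0))
        got = sum(l.kind == "provirus"
                  for l in pair_ltrs(hits, merge_fragments=False))
        agree += got == _max_pairing_bruteforce(hits)
    return {"agreement_pct": 100.0 * agree / n_instances}


def dating_recovery(seed: int = 0, n_per_age: int = 500,
                    ages_my=(1.0, 5.0, 10.0, 20.0),
                    rate: float = 2.7e-9, ltr_len: int = 1000) -> dict:
    """Two-LTR clock parameter recovery under the clean neutral model
    (no CpG hypermutation; the estimator runs unmasked - see
    docs/methods.md on the neutral-data bias of either-sequence CpG
    masking)."""
    rng = np.random.default_rng(seed)
    out = {}
    worst = 0.0
    for age_my in ages_my:
        age = age_my * 1e6
        ests = np.empty(n_per_age)
        for i in range(n_per_age):
            l5, l3 = simulate_ltr_pair(age, rng, ltr_len=ltr_len,
                                       rate=rate)
            div = ltr_divergence(l5, l3, exclude_cpg=False)
            ests[i] = age_from_divergence(div.d, rate)
        err_pct = 100.0 * abs(ests.mean() - age) / age
        out[f"mean_age_my_at_{age_my:g}"] = ests.mean() / 1e6
        worst = max(worst, err_pct)
    out["max_mean_error_pct"] = worst
    return out


def cpg_masking_benefit(seed: int = 0, n_replicates: int = 500,
                        age_years: float = 10e6,
                        cpg_multiplier: float = 10.0,
                        rate: float = 2.7e-9, ltr_len: int = 1000) -> dict:
    """Under CpG hypermutation, how often is the masked age estimate
    closer to truth than the unmasked one?"""
    rng = np.random.default_rng(seed)
    closer = 0
    for _ in range(n_replicates):
        l5, l3 = simulate_ltr_pair(age_years, rng, ltr_len=ltr_len,
                                   rate=rate,
                                   cpg_multiplier=cpg_multiplier)
        masked = age_from_divergence(ltr_divergence(l5, l3).d, rate)
        unmasked = age_from_divergence(
            ltr_divergence(l5, l3, exclude_cpg=False).d, rate)
        closer += abs(masked - age_years) < abs(unmasked - age_years)
    return {"masked_closer_pct": 100.0 * closer / n_replicates}


def orthology_recovery(seed: int = 0, n_ancestral: int = 10,
                       n_specific: int = 10,
                       split_years: float = 10e6) -> dict:
    """Two-species presence/absence calls scored against planted truth,
    with TSD recovery at empty sites."""
    events = tuple(
        [InsertionEvent(12e6, "infection", "ancestral")] * n_ancestral
        + [InsertionEvent(3e6, "retrotransposition", "A")] * n_specific
        + [InsertionEvent(3e6, "retrotransposition", "B")] * n_specific)
    cfg = SimConfig(seed=seed, genome_len=25_000 * len(events) + 100_000,
                    split_time_years=split_years,
                    insertion_events=events, solo_fraction=0.3)
    res = simulate(cfg)
    index = GenomeIndex(res.genome_b)
    truth = res.truth.set_index("locus_id")
    correct = total = 0
    absent_ok = absent_total = 0
    for locus in res.loci_a:
        lid = locus.locus_id.rsplit("_", 1)[0]
        row = truth.loc[lid]
        call = call_orthology(locus, res.genome_a, index,
                              res.config.ltr_len, "B")
        if row.present_b:
            expect = orthology.STATE_PROVIRUS if row.kind == "provirus" \
                else orthology.STATE_SOLO
        else:
            expect = orthology.STATE_ABSENT
        total += 1
        correct += call.state == expect
        if not row.present_b:
            absent_total += 1
            site = res.genome_b[0].sequence[int(row.start_b):
                                            int(row.end_b)]
            ok = (call.state == orthology.STATE_ABSENT
                  and call.gap is not None and call.gap <= 25
                  and call.tsd_seq == site and len(site) == 4)
            absent_ok += ok
    return {
        "n_calls": total,
        "state_accuracy_pct": 100.0 * correct / total,
        "n_empty_sites": absent_total,
        "empty_sites_with_tsd_pct": 100.0 * absent_ok
        / max(absent_total, 1),
    }


def conversion_detection(seed: int = 0, n_quartets: int = 500,
                         min_tract: float = 0.8,
                         support_threshold: float = 0.7) -> dict:
    """Recall and false-positive rate of the quartet test on simulated
    conversion (tract >= min_tract, both lineages) vs no conversion."""
    rng = np.random.default_rng(seed)
    n_conv = n_quartets // 2
    tp = fp = 0
    for i in range(n_quartets):
        if i < n_conv:
            tract = float(rng.uniform(min_tract, 1.0))
            case, _ = simulate_quartet(rng, conversion=(5e6, tract))
        else:
            case, _ = simulate_quartet(rng, conversion=None)
        v = quartet_topology(case, seed=seed + i)
        flagged = v.converted and v.support >= support_threshold
        if i < n_conv:
            tp += flagged
        else:
            fp += flagged
    return {
        "recall": tp / n_conv,
        "false_positive_rate": fp / (n_quartets - n_conv),
    }


def omega_recovery(seed: int = 0, omegas=(0.2, 0.5, 1.0),
                   n_replicates: int = 40) -> dict:
    """Counting-estimator bias on codon alignments simulated at known
    omega (star tree, 10 taxa, 300 codons)."""
    rng = np.random.default_rng(seed)
    out = {}
    worst = 0.0
    for om in omegas:
        ests = []
        for _ in range(n_replicates):
            aln = simulate_codon_alignment(rng, omega=om)
            arr = pair_codon_stats(aln)
            _, _, omega = _omega_from_sums(arr.sum(axis=1))
            ests.append(float(omega))
        err = abs(float(np.mean(ests)) - om)
        out[f"mean_omega_at_{om:g}"] = float(np.mean(ests))
        worst = max(worst, err)
    out["max_abs_error"] = worst
    return out


def neutrality_calibration(seed: int = 0, n_sims: int = 200,
                           alpha: float = 0.05) -> dict:
    """Rejection rate of the codon-bootstrap test on data simulated at
    omega = 1 (should be near the nominal level)."""
    rng = np.random.default_rng(seed)
    rejected = 0
    for i in range(n_sims):
        aln = simulate_codon_alignment(rng, omega=1.0)
        p = omega_neutrality_test(aln, seed=seed + i)
        rejected += p is not None and p < alpha
    return {"rejection_rate": rejected / n_sims}


def poisson_ci_coverage(seed: int = 0, n_draws: int = 10_000,
                        lambdas=(0.5, 2.0, 5.0, 20.0)) -> dict:
    """Empirical coverage of the exact Poisson CI, plus the zero-count
    upper bound against its closed form."""
    rng = np.random.default_rng(seed)
    worst = 1.0
    for lam in lambdas:
        k = rng.poisson(lam, size=n_draws)
        lo = np.where(k == 0, 0.0,
                      sp_stats.chi2.ppf(0.025, 2 * k) / 2.0)
        hi = sp_stats.chi2.ppf(0.975, 2 * k + 2) / 2.0
        cover = float(np.mean((lo <= lam) & (lam <= hi)))
        worst = min(worst, cover)
    zero_hi = poisson_ci(0, 1000)[1]
    return {
        "min_coverage_pct": 100.0 * worst,
        "zero_count_upper_x1000": 1000.0 * zero_hi,
    }


def shared_deletion_mirror(seed: int = 0, n_members: int = 43,
                           n_deleted: int = 29) -> dict:
    """A family in which a subset shares one envelope deletion: the
    breakpoint clustering should find exactly that subset."""
    rng = np.random.default_rng(seed)
    rows, ref = simulate_env_deletion_family(rng, n_members=n_members,
                                             n_deleted=n_deleted)
    clusters = shared_breakpoints(rows, ref)
    return {
        "n_clusters": len(clusters),
        "n_sharing": clusters[0].n_sharing if clusters else 0,
    }


def window_profile_checks(seed: int = 0) -> dict:
    """Window-count formula across lengths and the identity of a
    self-comparison."""
    rng = np.random.default_rng(seed)
    violations = 0
    for length in range(300, 2500, 73):
        aln = dating.PairwiseAlignment("A" * length, "A" * length)
        if len(dating.sliding_identity(aln)) != (length - 300) // 50 + 1:
            violations += 1
    seq = "".join(rng.choice(list("ACGT"), size=1000))
    profile = dating.sliding_identity(dating.PairwiseAlignment(seq, seq))
    return {
        "count_formula_violations": violations,
        "self_identity_min": float(profile.identity.min()),
    }
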