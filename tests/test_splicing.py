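"""Intron-centric psi/theta metrics, junction classification and concordance."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit, logit

from xconstraint.io_core import OrthologyMap
from xconstraint.splicing import (classify_junctions, compute_psi, compute_theta,
                                  constrained_flag, constrained_junctions,
                                  ortho_junction_concordance)


def jrow(start, end, sample, count, chrom="c", strand="+"):
    return {"chrom": chrom, "start": start, "end": end, "strand": strand,
            "sample": sample, "count": count}


class TestComputePsi:
    def test_hand_counted_toy_table(self):
        # main junction 8 reads; alternative acceptor from the same donor 2 reads
        jt = pd.DataFrame([jrow(100, 200, "s1", 8), jrow(100, 300, "s1", 2)])
        prof = compute_psi(jt, min_count=5).set_index("junction")
        main = prof.loc["c:100-200:+"]
        assert main["psi5"] == 8 / 10
        assert main["psi3"] == 1.0
        assert main["psi"] == 2 * 8 / (10 + 8)

    def test_min_count_gates_each_denominator(self):
        jt = pd.DataFrame([jrow(100, 200, "s1", 5)])
        with_10 = compute_psi(jt, min_count=10)
        assert np.isnan(with_10["psi"].iloc[0])
        with_5 = compute_psi(jt, min_count=5)
        assert with_5["psi"].iloc[0] == 1.0

    def test_negative_count_rejected(self):
        jt = pd.DataFrame([jrow(100, 200, "s1", -1)])
        with pytest.raises(ValueError, match="negative"):
            compute_psi(jt)

    def test_minus_strand_donor_is_intron_end(self):
        # two '-' junctions sharing the donor at the intron END coordinate
        jt = pd.DataFrame([jrow(100, 500, "s1", 30, strand="-"),
                           jrow(200, 500, "s1", 10, strand="-")])
        prof = compute_psi(jt).set_index("junction")
        assert prof.loc["c:100-500:-", "psi5"] == pytest.approx(0.75)
        assert prof.loc["c:200-500:-", "psi5"] == pytest.approx(0.25)

    def test_binomial_sampling_recovers_inclusion(self):
        rng = np.random.default_rng(13)
        reads = 1000
        n_inc = rng.binomial(reads, 0.3)
        jt = pd.DataFrame([jrow(100, 200, "s1", n_inc),
                           jrow(100, 300, "s1", reads - n_inc),
                           jrow(50, 200, "s1", reads - n_inc)])
        prof = compute_psi(jt).set_index("junction")
        assert abs(prof.loc["c:100-200:+", "psi"] - 0.3) <= 0.05

    def test_donor_psi5_sums_to_one(self, rng):
        """For any donor whose junctions all pass min_count, psi5 sums to 1."""
        rows = []
        for d in range(10):
            n_alt = int(rng.integers(2, 5))
            counts = rng.integers(10, 100, n_alt)
            for k in range(n_alt):
                rows.append(jrow(1000 * d, 1000 * d + 100 + 50 * k, "s1",
                                 int(counts[k])))
        prof = compute_psi(pd.DataFrame(rows), min_count=1)
        sums = prof.groupby("donor_site")["psi5"].sum()
        assert np.allclose(sums, 1.0)

    def test_pooled_psi_between_sided_estimates(self, rng):
        rows = []
        for d in range(20):
            rows.append(jrow(1000 * d, 1000 * d + 100, "s1", int(rng.integers(1, 50))))
            rows.append(jrow(1000 * d, 1000 * d + 200, "s1", int(rng.integers(1, 50))))
            rows.append(jrow(1000 * d - 500, 1000 * d + 100, "s1", int(rng.integers(1, 50))))
        prof = compute_psi(pd.DataFrame(rows), min_count=1).dropna(subset=["psi"])
        lo = np.minimum(prof["psi5"], prof["psi3"])
        hi = np.maximum(prof["psi5"], prof["psi3"])
        assert ((prof["psi"] >= lo - 1e-12) & (prof["psi"] <= hi + 1e-12)).all()
        assert prof["psi"].between(0, 1).all()


class TestComputeTheta:
    def boundaries(self, entries):
        return pd.DataFrame([{"chrom": "c", "pos": pos, "side": side,
                              "sample": "s1", "count": cnt}
                             for pos, side, cnt in entries])

    def test_hand_counted(self):
        jt = pd.DataFrame([jrow(100, 200, "s1", 90)])
        b = self.boundaries([(100, "donor", 10), (200, "acceptor", 10)])
        th = compute_theta(jt, b, min_count=1)
        assert th["theta"].iloc[0] == pytest.approx(180 / 200)

    def test_no_boundary_reads_means_complete_splicing(self):
        jt = pd.DataFrame([jrow(100, 200, "s1", 50)])
        b = self.boundaries([(100, "donor", 0), (200, "acceptor", 0)])
        assert compute_theta(jt, b, min_count=1)["theta"].iloc[0] == 1.0

    def test_unspliced_is_zero_or_na_by_min_count(self):
        jt = pd.DataFrame([jrow(100, 200, "s1", 0)])
        b = self.boundaries([(100, "donor", 30), (200, "acceptor", 30)])
        assert compute_theta(jt, b, min_count=10)["theta"].iloc[0] == 0.0
        b0 = self.boundaries([(100, "donor", 2), (200, "acceptor", 2)])
        assert np.isnan(compute_theta(jt, b0, min_count=10)["theta"].iloc[0])

    def test_missing_boundary_treated_as_zero(self):
        jt = pd.DataFrame([jrow(100, 200, "s1", 50)])
        b = self.boundaries([(100, "donor", 10)])  # acceptor record absent
        th = compute_theta(jt, b, min_count=1)
        assert th["theta"].iloc[0] == pytest.approx(100 / 110)


def profile_from_psi(psi_by_sample, junction="j1"):
    rows = []
    for sample, val in psi_by_sample.items():
        rows.append({"junction": junction, "sample": sample, "psi": val})
    return pd.DataFrame(rows)


class TestClassification:
    def species_map(self, samples):
        return {s: ("sp1" if s.startswith("h") else "sp2") for s in samples}

    def classify(self, psis):
        samples = [f"{'h' if i % 2 == 0 else 'm'}{i}" for i in range(len(psis))]
        prof = profile_from_psi(dict(zip(samples, psis)))
        return classify_junctions(prof, self.species_map(samples))["class"].iloc[0]

    def test_always_high_is_constitutive(self):
        assert self.classify([0.9, 0.92, 0.95, 0.99]) == "constitutive_high"

    def test_always_low_is_constitutive_low(self):
        assert self.classify([0.01, 0.05, 0.1, 0.02]) == "constitutive_low"

    def test_mixed_is_variable(self):
        assert self.classify([0.9, 0.5, 0.95, 0.9]) == "variable"

    def test_too_few_samples_unclassified(self):
        prof = profile_from_psi({"h1": 0.9, "h2": 0.9, "m1": 0.9})
        cls = classify_junctions(prof, self.species_map(["h1", "h2", "m1"]))
        assert cls["class"].iloc[0] == "unclassified"


class TestConstrainedFlag:
    def test_low_variance_intermediate_is_constrained(self):
        assert constrained_flag(0.5, 0.04)

    def test_alternating_blocks_exceed_variance_bound(self):
        psis = np.array([0.2, 0.8] * 4)
        m, v = psis.mean(), psis.var(ddof=1)
        assert m == 0.5 and v > 0.2 * m * (1 - m)
        assert not constrained_flag(m, v)

    def test_extreme_mean_outside_interval(self):
        assert not constrained_flag(0.95, 1e-6)

    def test_partitions_with_constitutive_classes(self, rng):
        """No junction is simultaneously constitutive and constrained-flagged."""
        samples = [f"h{i}" for i in range(4)] + [f"m{i}" for i in range(4)]
        rows = []
        for j in range(50):
            psis = rng.uniform(0, 1, 8)
            for s, p in zip(samples, psis):
                rows.append({"junction": f"j{j}", "sample": s, "psi": p})
        prof = pd.DataFrame(rows)
        smap = {s: ("sp1" if s.startswith("h") else "sp2") for s in samples}
        res = constrained_junctions(classify_junctions(prof, smap))
        bad = res[res["constrained_intermediate"]
                  & res["class"].isin(["constitutive_high", "constitutive_low"])]
        assert bad.empty


class TestConcordance:
    def random_profile(self, rng, n, prefix, psi=None):
        rows = []
        for j in range(n):
            for s in range(5):
                p = rng.uniform(0.05, 0.95) if psi is None else psi[j, s]
                rows.append({"junction": f"{prefix}{j}", "sample": f"s{s}", "psi": p})
        return pd.DataFrame(rows)

    def orth(self, n):
        return OrthologyMap(pairs=pd.DataFrame({
            "id1": [f"a{j}" for j in range(n)], "id2": [f"b{j}" for j in range(n)]}))

    def test_identical_profiles_correlate_perfectly(self, rng):
        psi = rng.uniform(0.1, 0.9, (50, 5))
        pa = self.random_profile(rng, 50, "a", psi)
        pb = self.random_profile(rng, 50, "b", psi)
        cc_mean, cc_sd = ortho_junction_concordance(pa, pb, self.orth(50))
        assert cc_mean == pytest.approx(1.0)
        assert cc_sd == pytest.approx(1.0)

    def test_independent_profiles_do_not_correlate(self):
        rng = np.random.default_rng(17)
        n = 5000
        pa = self.random_profile(rng, n, "a")
        pb = self.random_profile(rng, n, "b")
        cc_mean, cc_sd = ortho_junction_concordance(pa, pb, self.orth(n))
        assert abs(cc_mean) < 0.05

    def test_constant_complete_inclusion_excluded(self, rng):
        psi = rng.uniform(0.2, 0.8, (10, 5))
        psi[0, :] = 1.0  # constant complete inclusion must be dropped
        pa = self.random_profile(rng, 10, "a", psi)
        pb = self.random_profile(rng, 10, "b", psi)
        cc_mean, _ = ortho_junction_concordance(pa, pb, self.orth(10))
        assert np.isfinite(cc_mean)

    def test_shared_logit_signal_matches_attenuation(self):
        """cc of logit mean psi under shared latent + per-species noise matches
        a large-sample numerical evaluation of the same model within 0.05."""
        seed_model = dict(tau=1.2, omega=0.6, n_samples=5)

        def simulate(n, seed):
            rng = np.random.default_rng(seed)
            latent = rng.normal(0, seed_model["tau"], n)
            out = {}
            for sp in ("a", "b"):
                noise = rng.normal(0, seed_model["omega"], (n, seed_model["n_samples"]))
                out[sp] = expit(latent[:, None] + noise)
            return out

        sim = simulate(3000, 19)
        rows = {sp: [] for sp in sim}
        for sp in sim:
            for j in range(sim[sp].shape[0]):
                for s in range(sim[sp].shape[1]):
                    rows[sp].append({"junction": f"{sp}{j}", "sample": f"s{s}",
                                     "psi": sim[sp][j, s]})
        pa, pb = pd.DataFrame(rows["a"]), pd.DataFrame(rows["b"])
        orth = OrthologyMap(pairs=pd.DataFrame({
            "id1": [f"a{j}" for j in range(3000)],
            "id2": [f"b{j}" for j in range(3000)]}))
        cc_mean, _ = ortho_junction_concordance(pa, pb, orth)

        # independent large-n numerical oracle for the same generative model
        big = simulate(60_000, 999)
        def logit_means(mat):
            return logit(np.clip(mat.mean(axis=1), 1e-3, 1 - 1e-3))
        expect = stats.pearsonr(logit_means(big["a"]), logit_means(big["b"])).statistic
        assert abs(cc_mean - expect) <= 0.05
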