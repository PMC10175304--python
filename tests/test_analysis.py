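import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from chunkrt import analysis as an
from chunkrt.sequences import make_illusory_matrix


def _posterior_oracle(rt, mixture):
    """Brute-force component densities for one reaction time."""
    dens = [
        w * sps.norm.pdf(rt, m, s)
        for m, s, w in zip(mixture.means, mixture.sds, mixture.weights)
    ]
    return int(np.argmax(dens))


class TestFiltering:
    def test_fast_trials_kept(self, trials_builder):
        df = trials_builder(rts=[500, 900, 999])
        kept, frac = an.filter_trials(df)
        assert len(kept) == 3 and frac == 0.0

    def test_slow_trials_removed_and_fraction_reported(self, trials_builder):
        df = trials_builder(rts=[900, 1100])
        kept, frac = an.filter_trials(df)
        assert len(kept) == 1 and frac == pytest.approx(0.5)


class TestExclusion:
    def _participant(self, builder, pid, rt, acc, group="independent"):
        n = 40
        n_correct = int(round(acc * n))
        resp = "A" * n_correct + "B" * (n - n_correct)
        frames = [
            builder(participant=pid, group=group, instructions="A" * n,
                    responses=resp, rts=[rt] * n, block=1,
                    block_role="baseline"),
            builder(participant=pid, group=group, instructions="A" * n,
                    responses=resp, rts=[rt] * n, block=9, block_role="test"),
            builder(participant=pid, group=group, instructions="A" * n,
                    responses=resp, rts=[rt] * n, block=3,
                    block_role="training"),
        ]
        return pd.concat(frames, ignore_index=True)

    def test_experiment1_rules(self, trials_builder):
        df = pd.concat(
            [
                self._participant(trials_builder, "good", 600, 0.95),
                self._participant(trials_builder, "slow", 1100, 0.95),
                self._participant(trials_builder, "sloppy", 600, 0.80),
                self._participant(trials_builder, "edge", 1000, 0.90),
            ]
        )
        kept, report = an.exclude_participants(df, experiment=1)
        assert set(kept) == {"good", "edge"}  # thresholds are strict
        assert report.loc[report.participant == "slow", "excluded"].item()

    def test_experiment2_group_rules(self, trials_builder):
        fast_ok = self._participant(trials_builder, "f1", 600, 0.95, "fast")
        fast_slow = self._participant(trials_builder, "f2", 800, 0.95, "fast")
        acc_ok = self._participant(trials_builder, "a1", 600, 0.95, "accurate")
        df = pd.concat([fast_ok, fast_slow, acc_ok])
        kept, _ = an.exclude_participants(df, experiment=2)
        assert set(kept) == {"f1", "a1"}

    def test_unknown_experiment(self, trials_builder):
        with pytest.raises(ValueError):
            an.exclude_participants(trials_builder(), experiment=3)


class TestMixture:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(0)
        rts = np.concatenate(
            [rng.normal(300, 50, 300), rng.normal(500, 50, 300),
             rng.normal(800, 50, 300)]
        )
        mix = an.fit_rt_mixture(rts, seed=0)
        np.testing.assert_allclose(mix.means, [300, 500, 800], atol=20)
        assert np.all(np.diff(mix.means) > 0)

    def test_too_few_trials(self):
        with pytest.raises(ValueError):
            an.fit_rt_mixture(np.full(10, 400.0))

    def test_degenerate_cluster_engages_variance_floor(self):
        rts = np.full(60, 400.0) + np.random.default_rng(1).normal(0, 0.1, 60)
        mix = an.fit_rt_mixture(rts, seed=0)
        assert mix.variance_floored
        assert np.all(mix.sds > 0)

    def test_classification_matches_posterior_oracle(self, trials_builder):
        rng = np.random.default_rng(2)
        rts = np.concatenate(
            [rng.normal(320, 40, 120), rng.normal(520, 60, 120),
             rng.normal(820, 50, 60)]
        )
        mix = an.fit_rt_mixture(rts, seed=0)
        df = trials_builder(instructions="A" * len(rts), rts=rts)
        labels = an.classify_trials(df, mix)
        names = ["within", "between", "slow"]
        for rt, lab in zip(rts, labels):
            assert lab == names[_posterior_oracle(rt, mix)]

    def test_extreme_rts_get_extreme_labels(self, trials_builder):
        mix = an.RTMixture(
            means=np.array([300.0, 500.0, 800.0]),
            sds=np.array([50.0, 50.0, 50.0]),
            weights=np.array([1 / 3, 1 / 3, 1 / 3]),
        )
        df = trials_builder(instructions="AAA", rts=[300, 500, 2000])
        assert list(an.classify_trials(df, mix)) == ["within", "between", "slow"]


class TestChunkExtraction:
    def _profile(self, builder, responses, labels, **kw):
        df = builder(instructions=responses, responses=responses, **kw)
        return an.extract_chunks(df, labels)

    def test_between_within_runs(self, trials_builder):
        prof = self._profile(trials_builder, "ABCDA",
                             ["between", "within", "within", "between",
                              "within"])
        assert [c.symbols for c in prof.chunks] == ["ABC", "DA"]

    def test_all_between_gives_singletons(self, trials_builder):
        prof = self._profile(trials_builder, "ABCD", ["between"] * 4)
        assert [len(c) for c in prof.chunks] == [1, 1, 1, 1]

    def test_chunks_built_from_responses_not_instructions(self, trials_builder):
        df = trials_builder(instructions="ABDB", responses="ABDC",
                            rts=[400] * 4)
        prof = an.extract_chunks(
            df, ["between", "within", "within", "within"]
        )
        assert [c.symbols for c in prof.chunks] == ["ABDC"]

    def test_slow_trials_terminate_chunks(self, trials_builder):
        prof = self._profile(trials_builder, "ABCDE".replace("E", "A"),
                             ["between", "within", "slow", "within",
                              "within"])
        assert [c.symbols for c in prof.chunks] == ["AB", "DA"]

    def test_counts_match_brute_force(self, trials_builder):
        labels = ["between", "within", "between", "within", "within",
                  "between"]
        prof = self._profile(trials_builder, "ABABAB", labels)
        brute = sum(1 for c in prof.chunks if c.symbols == "AB")
        assert an.count_chunks(prof, "AB") == brute == 1

    def test_chunk_increase_and_sign_flip(self, trials_builder):
        base = trials_builder(instructions="ABAB", block=1,
                              block_role="baseline")
        test = trials_builder(instructions="ABABAB", block=9,
                              block_role="test")
        df = pd.concat([base, test], ignore_index=True)
        labels = ["between", "within"] * 5
        prof = an.extract_chunks(df, labels)
        assert an.chunk_increase(prof, "AB") == 1
        swapped = pd.concat([test.assign(block_role="baseline"),
                             base.assign(block_role="test")],
                            ignore_index=True)
        prof2 = an.extract_chunks(swapped, labels)
        assert an.chunk_increase(prof2, "AB") == -1


class TestCohensD:
    def test_identical_samples(self):
        x = [400, 420, 440]
        assert an.signed_cohens_d(x, x) == 0.0

    def test_one_pooled_sd_shift(self):
        rng = np.random.default_rng(3)
        x = rng.normal(500, 50, 2000)
        s = x.std(ddof=1)
        d = an.signed_cohens_d(x, x - s)
        assert d == pytest.approx(1.0, abs=1e-9)

    def test_swapping_negates(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(500, 40, 50), rng.normal(460, 40, 50)
        assert an.signed_cohens_d(x, y) == pytest.approx(
            -an.signed_cohens_d(y, x)
        )

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            an.signed_cohens_d([], [400])


class TestChunkyBoost:
    def _two_phase(self, builder, base_rt_map, test_rt_map, n_rep=20):
        """Alternating bigram blocks with per-bigram second-item RTs."""
        rng = np.random.default_rng(5)
        frames = []
        for role, block, rt_map in [("baseline", 1, base_rt_map),
                                    ("test", 9, test_rt_map)]:
            instructions = []
            rts = []
            for _ in range(n_rep):
                for bg, rt2 in rt_map.items():
                    instructions += [bg[0], bg[1]]
                    rts += [600 + rng.normal(0, 10), rt2 + rng.normal(0, 10)]
            frames.append(
                builder(instructions="".join(instructions), rts=rts,
                        block=block, block_role=role)
            )
        return pd.concat(frames, ignore_index=True)

    def test_zero_when_test_copies_baseline(self, trials_builder):
        rt_map = {"AB": 450, "BB": 480, "CB": 470, "DB": 460}
        base = self._two_phase(trials_builder, rt_map, rt_map)
        # make the test blocks literal copies of the baseline blocks
        test = base[base.block_role == "baseline"].assign(block_role="test",
                                                          block=9)
        df = pd.concat([base[base.block_role == "baseline"], test],
                       ignore_index=True)
        res = an.chunky_boost(df, "AB")
        assert res.value == pytest.approx(0.0, abs=1e-12)

    def test_positive_when_target_speeds_up(self, trials_builder):
        base = {"AB": 500, "BB": 500, "CB": 500, "DB": 500}
        test = {"AB": 380, "BB": 500, "CB": 500, "DB": 500}
        df = self._two_phase(trials_builder, base, test)
        res = an.chunky_boost(df, "AB")
        assert res.value > 0.5

    def test_control_sets(self):
        assert an.control_bigrams("AB", "second-item") == ["BB", "CB", "DB"]
        assert an.control_bigrams("AB", "first-item") == ["AA", "AC", "AD"]
        with pytest.raises(ValueError):
            an.control_bigrams("AB", "third-item")


class TestChunkiness:
    def test_zero_when_test_copies_baseline(self, trials_builder):
        rng = np.random.default_rng(6)
        instructions = "ABC" * 30 + "BCD" * 30
        rts = list(rng.normal(500, 60, len(instructions)))
        base = trials_builder(instructions=instructions, rts=rts, block=1,
                              block_role="baseline")
        test = base.assign(block_role="test", block=9)
        df = pd.concat([base, test], ignore_index=True)
        res = an.chunkiness(df, "ABC", control_trigrams_list=["BCD"])
        assert res.value == pytest.approx(0.0, abs=1e-12)

    def test_homogenisation_detected(self, trials_builder):
        """When the trigram's 2nd/3rd RTs converge at test, chunkiness > 0."""
        rng = np.random.default_rng(7)

        def phase(rt2, rt3, block, role):
            instructions = "ABCD" * 40
            rts = []
            for i, s in enumerate(instructions):
                if s == "B":
                    rts.append(rt2 + rng.normal(0, 5))
                elif s == "C":
                    rts.append(rt3 + rng.normal(0, 5))
                else:
                    rts.append(600 + rng.normal(0, 5))
            return trials_builder(instructions=instructions, rts=rts,
                                  block=block, block_role=role)

        df = pd.concat(
            [phase(400, 700, 1, "baseline"), phase(450, 460, 9, "test")],
            ignore_index=True,
        )
        res = an.chunkiness(df, "ABC", control_trigrams_list=["BCD"])
        assert res.value > 0

    def test_default_controls_exclude_target_and_repeats(self):
        controls = an.control_trigrams(["ABC"])
        assert "ABC" not in controls
        assert all(t[0] != t[1] and t[1] != t[2] for t in controls)
        assert len(controls) == 4 * 3 * 3 - 1


class TestChunkReuse:
    def _profile_from(self, symbol_list):
        chunks = [
            an.ExtractedChunk(s, "p1", 3, "training", i, i + len(s) - 1)
            for i, s in enumerate(symbol_list)
        ]
        return an.ChunkProfile("p1", chunks)

    def test_reuse_of_earlier_chunk(self):
        prof = self._profile_from(["BCD", "AB", "CDABCD"])
        assert an.chunk_reuse_probability(prof) == pytest.approx(0.5)

    def test_no_eligible_chunks_undefined(self):
        prof = self._profile_from(["AB", "CD", "A"])
        assert np.isnan(an.chunk_reuse_probability(prof))

    def test_repetition_chunks_ineligible(self):
        prof = self._profile_from(["ABC", "AABC"])
        # AABC has an immediate repetition, so only ABC (no history) counts
        assert an.chunk_reuse_probability(prof) == 0.0

    def test_window_limits_history(self):
        # the only reusable earlier chunk (BCD) sits just outside a
        # 30-chunk window filled with CA, which CDABCD does not contain
        prof = self._profile_from(["BCD"] + ["CA"] * 30 + ["CDABCD"])
        assert an.chunk_reuse_probability(prof, window=30) == pytest.approx(0.0)
        assert an.chunk_reuse_probability(prof, window=31) == pytest.approx(0.5)

    def test_all_reusing(self):
        prof = self._profile_from(["AB", "DAB", "ABD"])
        assert an.chunk_reuse_probability(prof) == 1.0


class TestRegressionTable:
    def test_chunkified_rows_one_hot(self):
        tr = make_illusory_matrix()
        c2 = an.chunkify_matrix(tr, ["AB"])
        np.testing.assert_allclose(c2.row("A"), [0, 1, 0, 0])
        np.testing.assert_allclose(c2.row("B"), tr.row("B"))
        c3 = an.chunkify_matrix(tr, ["AB", "BC"])
        np.testing.assert_allclose(c3.row("B"), [0, 0, 1, 0])
        np.testing.assert_allclose(c3.row("C"), tr.row("C"))
        unchanged = an.chunkify_matrix(tr, [])
        np.testing.assert_allclose(unchanged.probs, tr.probs)

    def test_design_table_contents(self, trials_builder):
        tr = make_illusory_matrix()
        df = trials_builder(instructions="ABCA", responses="ABCC",
                            rts=[400, 410, 420, 430], block=9,
                            block_role="test")
        table = an.build_rt_regressors(df, {"TR": tr})
        # first trial dropped; incorrect final trial dropped
        assert len(table) == 2
        assert table.iloc[0]["TR"] == pytest.approx(tr.entry("A", "B"))
        assert table.iloc[1]["TR"] == pytest.approx(tr.entry("B", "C"))
        np.testing.assert_allclose(
            table["log_rt"], np.log([410.0, 420.0])
        )

    def test_non_test_blocks_ignored(self, trials_builder):
        tr = make_illusory_matrix()
        df = trials_builder(instructions="ABCD", block=3,
                            block_role="training")
        assert an.build_rt_regressors(df, {"TR": tr}).empty
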