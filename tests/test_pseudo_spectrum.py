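"""The three-round cascade and greedy pseudo-spectrum generation."""

import numpy as np
import pytest

from tddemux.feature_model import SCPF, FragmentFeature, apex_cycle
from tddemux.pair_scoring import PairModel
from tddemux.pseudo_spectrum import (
    CascadeParams,
    estimate_fragment_quota,
    generate_window_pseudo_spectra,
    round1_filter,
    round2_filter,
    round3_filter,
    score_candidates,
)

from conftest import random_xic

K = 32


def _xic(apex, peak=100.0, sigma=1.5, k=K):
    cycles = np.arange(1, k + 1, dtype=float)
    x = peak * np.exp(-0.5 * ((cycles - apex) / sigma) ** 2)
    x[x < 0.01 * peak] = 0.0
    return x


def _scpf(apex=16, num_cycles_c=None, mass=9000.0, intensity=100.0, fid="S1"):
    if num_cycles_c is None:
        x = _xic(apex, intensity)
    else:  # rectangular XIC with exactly c observed cycles
        x = np.zeros(K)
        start = apex - (num_cycles_c // 2)
        x[start - 1 : start - 1 + num_cycles_c] = intensity
        x[apex - 1] = intensity * 2
    return SCPF(fid, fid, mass, 10, [(730.0, 1.0)], x)


def _frag(fid, apex, mass=800.0, intensity=50.0, window=1):
    return FragmentFeature(fid, window, mass, 1, _xic(apex, intensity))


#: Scoring model dominated by shared XIC: co-eluting fragments score ~1,
#: offset fragments ~0.  Used to steer round-2 deterministically.
STEEP_SHARED_MODEL = PairModel(np.array([0.0, 0.0, 40.0]), -20.0)


class TestRound1:
    def test_cutoff_is_min_of_t_and_half_c(self):
        scpf = _scpf(apex=16, num_cycles_c=4)  # c=4 -> cutoff min{3, 2} = 2
        kept = round1_filter(
            scpf, [_frag("F1", apex=18), _frag("F2", apex=19)], t=3
        )
        assert [f.feature_id for f in kept] == ["F1"]

    def test_single_cycle_scpf_keeps_only_co_apex_fragments(self):
        scpf = _scpf(apex=16, num_cycles_c=1)
        kept = round1_filter(
            scpf, [_frag("F1", apex=16), _frag("F2", apex=17)], t=3
        )
        assert [f.feature_id for f in kept] == ["F1"]

    def test_matches_brute_force_on_random_windows(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            scpf = SCPF("S1", "S1", 9000.0, 10, [(730.0, 1.0)], random_xic(rng, K))
            frags = [
                FragmentFeature(f"F{i}", 1, 500.0 + i, 1, random_xic(rng, K))
                for i in range(30)
            ]
            t = int(rng.integers(1, 5))
            cutoff = min(t, scpf.num_cycles // 2)
            expected = {
                f.feature_id
                for f in frags
                if abs(apex_cycle(f.xic) - apex_cycle(scpf.xic)) <= cutoff
            }
            assert {f.feature_id for f in round1_filter(scpf, frags, t)} == expected


class TestRound2:
    def _window(self, n_close, n_far):
        scpf = _scpf(apex=16)
        close = [_frag(f"C{i}", apex=16, mass=500.0 + i) for i in range(n_close)]
        far = [_frag(f"D{i}", apex=19, mass=2000.0 + i) for i in range(n_far)]
        return scpf, close + far

    def test_large_passing_subset_is_returned_as_is(self):
        scpf, L = self._window(30, 10)
        kept, fallback = round2_filter(scpf, L, STEEP_SHARED_MODEL)
        assert not fallback
        assert {f.feature_id for f, _ in kept} == {f"C{i}" for i in range(30)}

    def test_small_passing_subset_falls_back_to_top_25(self):
        scpf, L = self._window(10, 30)
        kept, fallback = round2_filter(scpf, L, STEEP_SHARED_MODEL)
        assert fallback
        assert len(kept) == 25
        # the 10 genuinely co-eluting fragments lead the fallback list
        assert {f.feature_id for f, _ in kept[:10]} == {f"C{i}" for i in range(10)}

    def test_short_candidate_list_is_returned_whole(self):
        scpf, L = self._window(3, 9)
        kept, fallback = round2_filter(scpf, L, STEEP_SHARED_MODEL)
        assert fallback
        assert len(kept) == 12

    def test_scores_are_sorted_descending(self):
        scpf, L = self._window(20, 20)
        kept, _ = round2_filter(scpf, L, STEEP_SHARED_MODEL)
        scores = [s for _, s in kept]
        assert scores == sorted(scores, reverse=True)


class TestFragmentQuota:
    def test_averagine_length_estimate(self):
        # 11112.54 Da / 111.1254 Da per residue = 100 residues -> T = 198
        assert estimate_fragment_quota(11112.54) == 198

    def test_small_mass_clamps_to_dipeptide(self):
        assert estimate_fragment_quota(111.1254) == 2

    def test_even_and_non_decreasing_in_mass(self):
        masses = np.linspace(200, 40000, 400)
        quotas = [estimate_fragment_quota(m) for m in masses]
        assert all(q % 2 == 0 for q in quotas)
        assert all(a <= b for a, b in zip(quotas, quotas[1:]))

    def test_non_positive_mass_rejected(self):
        with pytest.raises(ValueError):
            estimate_fragment_quota(0.0)


def _scored(n_low, n_high, rng):
    out = []
    for i in range(n_low):
        out.append((_frag(f"L{i}", 16, mass=300.0 + i), float(rng.uniform(0, 1))))
    for i in range(n_high):
        out.append((_frag(f"H{i}", 16, mass=2000.0 + i), float(rng.uniform(0, 1))))
    return out


def _round3_oracle(scored, T, bound=1500.0, low_quota=25):
    low = [fs for fs in scored if fs[0].mono_mass < bound]
    high = [fs for fs in scored if fs[0].mono_mass >= bound]
    key = lambda fs: (-fs[1], fs[0].mono_mass, fs[0].feature_id)
    return sorted(low, key=key)[: min(low_quota, T)] + sorted(high, key=key)[
        : max(0, T - low_quota)
    ]


class TestRound3:
    def test_quota_arithmetic_25_low_plus_T_minus_25_high(self):
        rng = np.random.default_rng(2)
        out = round3_filter(_scored(60, 300, rng), 198)
        masses = [f.mono_mass for f, _ in out]
        assert sum(m < 1500 for m in masses) == 25
        assert sum(m >= 1500 for m in masses) == 173

    def test_non_binding_quotas_keep_everything(self):
        rng = np.random.default_rng(3)
        out = round3_filter(_scored(10, 10, rng), 198)
        assert len(out) == 20

    def test_small_T_clamps_low_quota_and_zeroes_high(self):
        rng = np.random.default_rng(4)
        out = round3_filter(_scored(60, 300, rng), 20)
        assert len(out) == 20
        assert all(f.mono_mass < 1500 for f, _ in out)

    def test_matches_brute_force_on_random_inputs(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            scored = _scored(int(rng.integers(0, 40)), int(rng.integers(0, 80)), rng)
            T = int(rng.integers(2, 120))
            got = round3_filter(scored, T)
            want = _round3_oracle(scored, T)
            assert [f.feature_id for f, _ in got] == [f.feature_id for f, _ in want]


def _reference_cascade(fragments, scpfs, model, params):
    """Independent plain-loop reimplementation of the greedy cascade."""
    remaining = list(fragments)
    result = {}
    for scpf in sorted(
        scpfs, key=lambda s: (-s.total_intensity, s.mono_mass, s.feature_id)
    ):
        cutoff = min(params.t, scpf.num_cycles // 2)
        L = [
            f
            for f in remaining
            if abs(apex_cycle(f.xic) - apex_cycle(scpf.xic)) <= cutoff
        ]
        if not L:
            continue
        scores = dict(zip([f.feature_id for f in L], score_candidates(scpf, L, model)))
        ranked = sorted(
            L, key=lambda f: (-scores[f.feature_id], f.mono_mass, f.feature_id)
        )
        passing = [f for f in ranked if scores[f.feature_id] > params.score_cutoff]
        survivors = passing if len(passing) >= params.min_keep else ranked[: params.min_keep]
        T = estimate_fragment_quota(scpf.mono_mass, params.avg_residue_mass)
        low = [f for f in survivors if f.mono_mass < params.low_mass_bound]
        high = [f for f in survivors if f.mono_mass >= params.low_mass_bound]
        chosen = low[: min(params.low_quota, T)] + high[: max(0, T - params.low_quota)]
        result[scpf.feature_id] = {f.feature_id for f in chosen}
        remaining = [f for f in remaining if f.feature_id not in result[scpf.feature_id]]
    return result


class TestGreedyGeneration:
    def test_shared_fragment_goes_to_the_more_intense_scpf(self):
        strong = _scpf(apex=16, intensity=200.0, fid="S_strong")
        weak = _scpf(apex=16, intensity=50.0, fid="S_weak")
        shared = _frag("F_shared", apex=16)
        specs = generate_window_pseudo_spectra(
            [shared], [weak, strong], STEEP_SHARED_MODEL
        )
        by_id = {s.scpf_id: s for s in specs}
        assert "F_shared" in by_id["S_strong"].fragment_ids
        assert "S_weak" not in by_id or "F_shared" not in by_id.get("S_weak").fragment_ids

    def test_single_scpf_equals_plain_cascade(self, trained_model):
        rng = np.random.default_rng(8)
        scpf = _scpf(apex=16)
        frags = [
            _frag(f"F{i}", apex=int(rng.integers(12, 21)), mass=float(rng.uniform(300, 5000)))
            for i in range(60)
        ]
        params = CascadeParams()
        specs = generate_window_pseudo_spectra(frags, [scpf], trained_model, params)
        ref = _reference_cascade(frags, [scpf], trained_model, params)
        assert len(specs) == 1
        assert specs[0].fragment_ids == ref["S1"]

    def test_matches_reference_on_random_small_windows(self, trained_model):
        rng = np.random.default_rng(9)
        params = CascadeParams()
        for trial in range(10):
            scpfs = [
                SCPF(
                    f"S{i}",
                    f"S{i}",
                    float(rng.uniform(5000, 20000)),
                    10,
                    [(730.0, 1.0)],
                    random_xic(rng, K),
                )
                for i in range(int(rng.integers(1, 6)))
            ]
            frags = [
                FragmentFeature(
                    f"F{i}", 1, float(rng.uniform(300, 6000)), 1, random_xic(rng, K)
                )
                for i in range(int(rng.integers(10, 200)))
            ]
            specs = generate_window_pseudo_spectra(frags, scpfs, trained_model, params)
            ref = _reference_cascade(frags, scpfs, trained_model, params)
            assert {s.scpf_id for s in specs} == set(ref)
            for s in specs:
                assert s.fragment_ids == ref[s.scpf_id]

    def test_fragment_sets_disjoint_and_size_bounded(self, trained_model):
        rng = np.random.default_rng(10)
        scpfs = [
            SCPF(f"S{i}", f"S{i}", 8000.0 + i, 10, [(730.0, 1.0)], random_xic(rng, K))
            for i in range(5)
        ]
        frags = [
            FragmentFeature(f"F{i}", 1, float(rng.uniform(300, 6000)), 1, random_xic(rng, K))
            for i in range(300)
        ]
        specs = generate_window_pseudo_spectra(frags, scpfs, trained_model)
        seen: set[str] = set()
        for s in specs:
            assert not (s.fragment_ids & seen)
            seen |= s.fragment_ids
            T = estimate_fragment_quota(s.precursor_mass)
            assert 0 < len(s.fragments) <= max(T, 25)

    def test_equal_intensity_ties_are_deterministic(self, trained_model):
        rng = np.random.default_rng(12)
        x = random_xic(rng, K)
        scpfs = [
            SCPF(f"S{i}", f"S{i}", 8000.0 + i, 10, [(730.0, 1.0)], x.copy())
            for i in range(3)
        ]  # identical XICs -> identical intensities; masses differ
        frags = [
            FragmentFeature(f"F{i}", 1, float(rng.uniform(300, 6000)), 1, random_xic(rng, K))
            for i in range(80)
        ]
        a = generate_window_pseudo_spectra(frags, scpfs, trained_model)
        b = generate_window_pseudo_spectra(frags, list(reversed(scpfs)), trained_model)
        assert [(s.scpf_id, sorted(s.fragment_ids)) for s in a] == [
            (s.scpf_id, sorted(s.fragment_ids)) for s in b
        ]

    def test_duplicate_fragment_ids_rejected(self, trained_model):
        f = _frag("F1", 16)
        with pytest.raises(ValueError, match="duplicate fragment id"):
            generate_window_pseudo_spectra([f, f], [_scpf()], trained_model)
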