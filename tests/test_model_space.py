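"""Model-space enumeration and the sign-producibility pruning rule."""

import itertools

import numpy as np
import pytest

from costevidence.core_model import (
    FactorLevels,
    InvalidParameterRegion,
    ModelCoefficients,
    ParamCoefficients,
    compute_latent_params,
    predict_durations,
)
from costevidence.model_space import (
    EffectRequirement,
    ModulationConfig,
    can_produce,
    enumerate_full_space,
    load_space_frame,
    prune_space,
    pruned_space,
    space_to_frame,
    task_requirements,
    winning_config,
)

BOTH = frozenset({"Te", "Tr"})


class TestEnumeration:
    @pytest.mark.parametrize(
        "family,factors,expected",
        [
            ("linear", ("incentive", "actual"), 64),
            ("linear", ("incentive", "actual", "cued"), 512),
            ("hyperbolic", ("incentive", "actual", "cued"), 216),
        ],
    )
    def test_full_space_sizes(self, family, factors, expected):
        assert len(enumerate_full_space(family, factors)) == expected

    def test_hyperbolic_excludes_denominator_without_numerator(self):
        space = enumerate_full_space("hyperbolic", ("incentive", "actual", "cued"))
        for config in space:
            for p in ("A", "Se", "Sr"):
                if config.has(p, "cued"):
                    assert config.has(p, "incentive")

    def test_hyperbolic_without_cue_factor_rejected(self):
        with pytest.raises(ValueError):
            enumerate_full_space("hyperbolic", ("incentive", "actual"))

    def test_no_duplicates_and_stable_order(self):
        s1 = enumerate_full_space("linear", ("incentive", "actual"))
        s2 = enumerate_full_space("linear", ("incentive", "actual"))
        assert s1.configs == s2.configs
        assert len(set(s1.configs)) == len(s1)


class TestCanProduce:
    def test_amplitude_only_cannot_give_opposite_signs(self):
        config = ModulationConfig("linear", frozenset({("A", "incentive")}))
        req = EffectRequirement("incentive", BOTH, "opposite-sign")
        assert not can_produce(config, req)

    def test_amplitude_plus_slope_can_give_opposite_signs(self):
        config = ModulationConfig(
            "linear", frozenset({("A", "incentive"), ("Se", "incentive")})
        )
        req = EffectRequirement("incentive", BOTH, "opposite-sign")
        assert can_produce(config, req)

    def test_no_pathway_fails_any_requirement(self):
        config = ModulationConfig("linear", frozenset())
        assert not can_produce(
            config, EffectRequirement("incentive", frozenset({"Te"}))
        )

    def _numeric_sign_patterns(self, config, factor, rng, n_draws=400):
        """Brute-force oracle: achievable sign patterns of the factor's
        effect on (Te, Tr) under random signed weights."""
        patterns = set()
        base = FactorLevels(0.3, 0.8, 0.8)
        bumped = FactorLevels(
            0.3 + (0.05 if factor == "incentive" else 0),
            0.8 + (0.05 if factor == "actual" else 0),
            0.8 + (0.05 if factor == "cued" else 0),
        )
        for _ in range(n_draws):
            fields = {p: {"mean": rng.uniform(2.0, 4.0)} for p in ("A", "Se", "Sr")}
            for p, f in config.flags:
                w = rng.uniform(0.2, 1.5) * rng.choice([-1, 1])
                key = {"incentive": "incentive", "actual": "actual", "cued": "cued"}[f]
                fields[p][key] = w
            try:
                coeffs = ModelCoefficients(
                    "linear", **{p: ParamCoefficients(**kw) for p, kw in fields.items()}
                )
                p0 = predict_durations(compute_latent_params(coeffs, base))
                p1 = predict_durations(compute_latent_params(coeffs, bumped))
            except (InvalidParameterRegion, ValueError):
                continue
            patterns.add(
                (int(np.sign(round(p1.Te - p0.Te, 12))), int(np.sign(round(p1.Tr - p0.Tr, 12))))
            )
        return patterns

    def test_agrees_with_random_weight_oracle(self, rng):
        factors = ("incentive", "actual")
        space = enumerate_full_space("linear", factors)
        picked = [space.configs[i] for i in rng.choice(len(space), 12, replace=False)]
        for config in picked:
            for factor in factors:
                patterns = self._numeric_sign_patterns(config, factor, rng)
                opposite = {(1, -1), (-1, 1)} & patterns != set()
                affects_te = any(s[0] != 0 for s in patterns)
                affects_tr = any(s[1] != 0 for s in patterns)
                req_te = EffectRequirement(factor, frozenset({"Te"}))
                req_tr = EffectRequirement(factor, frozenset({"Tr"}))
                req_opp = EffectRequirement(factor, BOTH, "opposite-sign")
                assert can_produce(config, req_te) == affects_te
                assert can_produce(config, req_tr) == affects_tr
                assert can_produce(config, req_opp) == opposite


class TestPrunedSpaces:
    @pytest.mark.parametrize(
        "task,expected",
        [
            ("implicit", 24),
            ("explicit", 16),
            ("dissociation", 144),
            ("explicit_hyperbolic", 78),
            ("dissociation_hyperbolic", 78),
        ],
    )
    def test_pruned_counts(self, task, expected):
        assert len(pruned_space(task)) == expected

    def test_pruning_is_idempotent_and_a_subset(self):
        space = enumerate_full_space("linear", ("incentive", "actual"))
        reqs = task_requirements("implicit")
        once = prune_space(space, reqs)
        twice = prune_space(once, reqs)
        assert once.configs == twice.configs
        assert set(once.configs) <= set(space.configs)

    @pytest.mark.parametrize(
        "task", ["implicit", "explicit_hyperbolic", "dissociation_hyperbolic"]
    )
    def test_selected_configuration_survives_pruning(self, task):
        assert winning_config(task) in pruned_space(task).configs

    def test_hyperbolic_count_by_filtering_construction(self):
        # independent route: count per-parameter (incentive, cued, actual)
        # term combinations directly instead of via the space machinery
        count = 0
        options = [
            (i, c, a)
            for i, c, a in itertools.product((0, 1), repeat=3)
            if not (c and not i)
        ]
        assert len(options) == 6
        for combo in itertools.product(options, repeat=3):
            inc = {p for p, o in zip("ABC", combo) if o[0]}
            cued = {p for p, o in zip("ABC", combo) if o[1]}
            act = {p for p, o in zip("ABC", combo) if o[2]}
            # A->'A' amplitude, B->'Se', C->'Sr'
            ok_inc = (
                len(inc) >= 2 and inc & {"A", "B"} != set() and inc & {"A", "C"} != set()
            )
            ok_act = act & {"A", "B"} != set()
            ok_cued = cued & {"A", "C"} != set()
            count += ok_inc and ok_act and ok_cued
        assert count == 78

    def test_flag_matrix_round_trip(self):
        space = pruned_space("implicit")
        frame = space_to_frame(space)
        assert len(frame) == 24
        assert frame.filter(like="_cued").to_numpy().sum() == 0
        recovered = load_space_frame(frame)
        assert recovered.configs == space.configs
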