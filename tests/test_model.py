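"""Mass-action RHS generation, integration accuracy, and feature extraction."""

import numpy as np
import pandas as pd
import pytest

from kincal import (
    DynamicFeatures,
    ModelDefinitionError,
    OdeModel,
    Species,
    Trajectory,
    build_rhs,
    extract_features,
    load_model,
    parse_reaction,
    save_model,
    simulate,
)


class TestReactionParsing:
    @pytest.mark.parametrize(
        "text, reactants, products, k",
        [
            ("A -> B @ k1", (("A", 1),), (("B", 1),), "k1"),
            ("A + B -> C @ k2", (("A", 1), ("B", 1)), (("C", 1),), "k2"),
            ("2 A -> A2 @ kd", (("A", 2),), (("A2", 1),), "kd"),
            ("A -> 0 @ kdeg", (("A", 1),), (), "kdeg"),
            ("0 -> A @ ksyn", (), (("A", 1),), "ksyn"),
        ],
    )
    def test_roundtrip(self, text, reactants, products, k):
        rxn = parse_reaction(text)
        assert rxn.reactants == reactants
        assert rxn.products == products
        assert rxn.rate_constant == k

    def test_malformed_reaction_rejected(self):
        with pytest.raises(ModelDefinitionError):
            parse_reaction("A + -> B @ k")
        with pytest.raises(ModelDefinitionError):
            parse_reaction("A -> B")


class TestModelValidation:
    def test_unknown_species_named_in_error(self):
        with pytest.raises(ModelDefinitionError, match="Ghost"):
            OdeModel(
                species=(Species("A", 1.0),),
                reactions=(parse_reaction("A -> Ghost @ k"),),
                parameters={"k": 1.0},
            )

    def test_unknown_rate_constant_named_in_error(self):
        with pytest.raises(ModelDefinitionError, match="k_missing"):
            OdeModel(
                species=(Species("A", 1.0),),
                reactions=(parse_reaction("A -> 0 @ k_missing"),),
                parameters={"k_other": 1.0},
            )

    def test_negative_initial_concentration_rejected(self):
        with pytest.raises(ModelDefinitionError):
            Species("A", -0.5)

    def test_duplicate_species_rejected(self):
        with pytest.raises(ModelDefinitionError, match="duplicate"):
            OdeModel(species=(Species("A"), Species("A")), reactions=(),
                     parameters={})


class TestRhs:
    def test_single_mass_action_reaction(self):
        model = OdeModel(
            species=(Species("A", 3.0), Species("B", 0.0)),
            reactions=(parse_reaction("A -> B @ k"),),
            parameters={"k": 2.0},
        )
        rhs = build_rhs(model)
        dy = rhs(0.0, np.array([3.0, 0.0]), np.array([2.0]))
        assert dy == pytest.approx([-6.0, 6.0])

    def test_bimolecular_rate_law(self):
        model = OdeModel(
            species=(Species("A", 2.0), Species("B", 4.0), Species("C")),
            reactions=(parse_reaction("A + B -> C @ k"),),
            parameters={"k": 0.5},
        )
        dy = build_rhs(model)(0.0, np.array([2.0, 4.0, 0.0]), np.array([0.5]))
        assert dy == pytest.approx([-4.0, -4.0, 4.0])

    def test_zero_state_gives_zero_derivative(self, cascade):
        rhs = build_rhs(cascade)
        p = np.array([cascade.parameters[k] for k in cascade.parameter_ids])
        dy = rhs(0.0, np.zeros(len(cascade.species)), p)
        assert np.allclose(dy, 0.0)

    def test_cascade_rhs_matches_hand_expansion(self, cascade):
        """Term-by-term expansion of the fixture's reaction list."""
        rng = np.random.default_rng(0)
        y = rng.uniform(0.0, 5.0, len(cascade.species))
        p = np.array([cascade.parameters[k] for k in cascade.parameter_ids])
        expected = np.zeros_like(y)
        pidx = {pid: i for i, pid in enumerate(cascade.parameter_ids)}
        for rxn in cascade.reactions:
            rate = p[pidx[rxn.rate_constant]]
            for name, st in rxn.reactants:
                rate *= y[cascade.species_index(name)] ** st
            for name, st in rxn.reactants:
                expected[cascade.species_index(name)] -= st * rate
            for name, st in rxn.products:
                expected[cascade.species_index(name)] += st * rate
        got = build_rhs(cascade)(0.0, y, p)
        assert np.allclose(got, expected, rtol=1e-12)


class TestSimulate:
    def test_exponential_decay_closed_form(self, decay_model):
        grid = np.linspace(0.0, 10.0, 11)
        traj = simulate(decay_model, grid=grid)
        expected = np.exp(-0.1 * grid)
        assert np.allclose(traj.get("amount"), expected, rtol=1e-6)
        assert traj.get("amount")[-1] == pytest.approx(np.exp(-1.0), rel=1e-6)

    def test_reversible_conversion_closed_form(self, conversion_model):
        # A(t) for A<->B relaxes to kr*T/(kf+kr) with rate kf+kr
        grid = np.linspace(0.0, 20.0, 41)
        traj = simulate(conversion_model, grid=grid)
        kf, kr, total = 0.3, 0.1, 2.0
        a_inf = kr * total / (kf + kr)
        expected = a_inf + (2.0 - a_inf) * np.exp(-(kf + kr) * grid)
        assert np.allclose(traj.get("A"), expected, rtol=1e-6, atol=1e-9)

    def test_conservation_pool_constant(self, conversion_model):
        traj = simulate(conversion_model, horizon=50.0)
        total = traj.get("A") + traj.get("B")
        assert np.allclose(total, 2.0, rtol=1e-6)

    def test_cascade_mass_conservation(self, cascade, reporter_grid):
        traj = simulate(cascade.with_initial(L=250.0), grid=reporter_grid)
        for members in cascade.pools.values():
            pool = sum(traj.get(m) for m in members)
            assert np.allclose(pool, pool[0], rtol=1e-6)

    def test_parameter_override_mapping(self, decay_model):
        traj = simulate(decay_model, {"k": 0.2}, grid=np.array([0.0, 5.0]))
        assert traj.get("amount")[-1] == pytest.approx(np.exp(-1.0), rel=1e-6)

    def test_monotone_cleavage_at_top_dose(self, cascade, reporter_grid):
        traj = simulate(cascade.with_initial(L=250.0), grid=reporter_grid)
        frac = traj.get("cleaved_fraction")
        assert np.all(np.diff(frac) >= -1e-9)
        assert frac[-1] > 0.99

    def test_tidy_export_schema(self, decay_model):
        traj = simulate(decay_model, grid=np.linspace(0, 5, 6),
                        condition_label="ctrl")
        tidy = traj.to_tidy()
        assert list(tidy.columns) == ["condition", "time_min", "observable", "value"]
        assert set(tidy["condition"]) == {"ctrl"}
        assert len(tidy) == 6


class TestFeatures:
    @staticmethod
    def _traj(times, values):
        frame = pd.DataFrame({"cleaved_fraction": values},
                             index=pd.Index(times, name="time_min"))
        return Trajectory(times=np.asarray(times, float), values=frame,
                          states=frame)

    def test_linear_ramp_interpolated_delay(self):
        feats = extract_features(self._traj([0.0, 100.0], [0.0, 1.0]))
        assert feats.t_delay == pytest.approx(50.0)
        assert feats.dead

    def test_flat_trajectory_never_dies(self):
        feats = extract_features(self._traj([0.0, 50.0, 100.0], [0.2, 0.2, 0.2]))
        assert feats.t_delay is None
        assert not feats.dead

    def test_interpolation_between_samples(self):
        times = [0.0, 177.0, 180.0, 300.0]
        values = [0.0, 0.4, 0.6, 1.0]
        feats = extract_features(self._traj(times, values))
        assert feats.t_delay == pytest.approx(178.5)

    def test_switch_width_on_linear_ramp(self):
        # 10% to 90% of a 0->1 ramp over 100 min spans 80 min
        feats = extract_features(self._traj([0.0, 100.0, 200.0], [0.0, 1.0, 1.0]))
        assert feats.t_switch == pytest.approx(80.0)

    def test_missing_observable_raises(self, decay_model):
        traj = simulate(decay_model, grid=np.linspace(0, 5, 6))
        from kincal import FeatureError
        with pytest.raises(FeatureError):
            extract_features(traj, observable="cleaved_fraction")

    def test_dose_never_increases_delay(self, cascade, reporter_grid):
        delays = []
        for dose in (10.0, 50.0, 250.0):
            traj = simulate(cascade.with_initial(L=dose), grid=reporter_grid)
            delays.append(extract_features(traj).t_delay)
        assert all(d is not None for d in delays)
        assert delays[0] > delays[1] > delays[2]


class TestModelFile:
    def test_roundtrip_preserves_everything(self, cascade, tmp_path):
        path = tmp_path / "cascade.kincal"
        save_model(cascade, path)
        loaded = load_model(path)
        assert loaded.species == cascade.species
        assert loaded.reactions == cascade.reactions
        assert loaded.parameters == cascade.parameters
        assert loaded.observables == cascade.observables
        assert loaded.pools == cascade.pools

    def test_header_required(self, tmp_path):
        path = tmp_path / "bad.kincal"
        path.write_text("species A 1.0\n")
        with pytest.raises(ModelDefinitionError, match="header"):
            load_model(path)
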