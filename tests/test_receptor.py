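"""Receptor-layer kinetics: stoichiometric exactness and dynamic structure."""

import numpy as np
import pytest

from bcellfate.receptor import (
    N_SPECIES,
    PHI_DEFAULTS,
    SPECIES,
    ConfigurationError,
    InvalidStateError,
    ReceptorParams,
    ReceptorState,
    conservation_totals,
    default_initial_array,
    find_steady_state,
    load_rate_table,
    receptor_derivatives,
    receptor_rhs,
    simulate_receptor,
    write_rate_table,
)
from bcellfate.stimulus import LigandPulse, StimulationProtocol, constant_stimulation

IDX = {name: i for i, name in enumerate(SPECIES)}

# Independently hand-assembled kinetic scheme, re-typed reaction by reaction
# from the rate table: (rate index, mass-action species, {species: coeff}),
# where the string "c" marks a medium-facing coefficient to be multiplied by
# the medium-to-cell scaling factor.  Reaction 37 carries the Hill gate.
ORACLE_SCHEME = [
    (1, ["ANTIGEN"], {"ANTIGEN": -1}),
    (2, [], {"BCR": 1}),
    (3, ["BCR"], {"BCR": -1}),
    (4, ["ANTIGEN", "BCR"], {"ANTIGEN": "-c", "BCR": -1, "ABCR": 1}),
    (5, ["ABCR"], {"ABCR": -1, "ANTIGEN": "+c", "BCR": 1}),
    (6, ["ABCR"], {"ABCR": -1}),
    (7, ["CBM", "ABCR"], {"CBM": -1, "ACBM": 1}),
    (8, ["ACBM"], {"ACBM": -1, "CBM": 1}),
    (9, ["ACBM", "IKK2"], {"ACBM": -1, "ICBM": 1}),
    (10, ["ICBM"], {"ICBM": -1, "CBM": 1}),
    (11, ["CD40L"], {"CD40L": -1}),
    (12, [], {"CD40R": 1}),
    (13, ["CD40R"], {"CD40R": -1}),
    (14, ["CD40L", "CD40R"], {"CD40L": "-c", "CD40R": -1, "CD40LR": 1}),
    (15, ["CD40LR"], {"CD40LR": -1, "CD40L": "+c", "CD40R": 1}),
    (16, ["CD40LR"], {"CD40LR": -1}),
    (17, ["CD40LR", "TRAF6_off"], {"TRAF6_off": -1, "TRAF6": 1}),
    (18, ["TRAF6"], {"TRAF6": -1, "TRAF6_off": 1}),
    (19, [], {"TRAF3": 1}),
    (20, ["TRAF3"], {"TRAF3": -1}),
    (21, ["CD40LR", "TRAF3"], {"TRAF3": -1}),
    (22, ["ACBM", "TAK1"], {"TAK1": -1, "ATAK1": 1}),
    (23, ["TRAF6", "TAK1"], {"TAK1": -1, "ATAK1": 1}),
    (24, ["IKK2", "TAK1"], {"TAK1": -1, "ATAK1": 1}),
    (25, ["IKK3", "TAK1"], {"TAK1": -1, "ATAK1": 1}),
    (26, ["TAK1"], {"TAK1": -1, "ATAK1": 1}),
    (27, ["ATAK1"], {"ATAK1": -1, "TAK1": 1}),
    (28, ["ATAK1", "IKK_off"], {"IKK_off": -1, "IKK2": 1}),
    (29, ["IKK2"], {"IKK2": -1, "IKK_off": 1}),
    (30, ["IKK2"], {"IKK2": -1, "IKK3": 1}),
    (31, ["IKK3", "IKK2"], {"IKK2": -1, "IKK3": 1}),
    (32, ["IKK3"], {"IKK3": -1, "IKK2": 1}),
    (33, ["IKK3"], {"IKK3": -1, "IIKK": 1}),
    (34, ["IIKK"], {"IIKK": -1, "IKK_off": 1}),
    (35, [], {"NIK": 1}),
    (36, ["NIK"], {"NIK": -1}),
    (37, ["NIK", "HILL_TRAF3"], {"NIK": -1}),
]


def oracle_derivatives(y: np.ndarray, params: ReceptorParams) -> np.ndarray:
    """Brute-force flux-by-flux evaluation of the kinetic scheme."""
    dy = np.zeros(N_SPECIES)
    for idx, factors, stoich in ORACLE_SCHEME:
        flux = params.phi[idx]
        for f in factors:
            if f == "HILL_TRAF3":
                t3 = y[IDX["TRAF3"]]
                n = params.n_traf3_hill
                flux *= t3 ** n / (t3 ** n + params.k_traf3_half ** n) if t3 > 0 else 0.0
            else:
                flux *= y[IDX[f]]
        for species, coeff in stoich.items():
            if coeff == "-c":
                dy[IDX[species]] -= flux * params.c_c2m
            elif coeff == "+c":
                dy[IDX[species]] += flux * params.c_c2m
            else:
                dy[IDX[species]] += coeff * flux
    return dy


class TestDerivatives:
    def test_synthesis_only_terms_at_empty_state(self, receptor_params):
        """With every species absent, only the constant-synthesis reactions
        contribute: BCR, CD40R, TRAF3 and NIK production."""
        d = receptor_derivatives(np.zeros(N_SPECIES), receptor_params)
        assert d["BCR"] == pytest.approx(4.93, abs=0)
        assert d["CD40R"] == pytest.approx(7.672, abs=0)
        assert d["NIK"] == pytest.approx(12.0, abs=0)
        assert d["TRAF3"] == pytest.approx(10.0, abs=0)

    def test_empty_conserved_pools_have_zero_derivative(self, receptor_params):
        d = receptor_derivatives(np.zeros(N_SPECIES), receptor_params)
        for name in ("CBM", "ACBM", "ICBM", "TAK1", "ATAK1",
                     "IKK2", "IKK3", "IIKK"):
            assert d[name] == 0.0

    def test_matches_stoichiometric_oracle_on_random_states(self, receptor_params, rng):
        """The hand-coded right-hand side equals the per-reaction flux sum
        (flux = rate x product of reactants; derivative = stoichiometry x
        flux) on 1000 random positive states to 1e-12 relative."""
        for _ in range(1000):
            y = rng.uniform(0.0, 50.0, size=N_SPECIES)
            got = receptor_rhs(y, receptor_params)
            want = oracle_derivatives(y, receptor_params)
            np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-8)

    def test_rejects_negative_state_and_unknown_species(self, receptor_params):
        y = np.zeros(N_SPECIES)
        y[0] = -1e-6
        with pytest.raises(InvalidStateError):
            receptor_derivatives(y, receptor_params)
        with pytest.raises(ConfigurationError):
            ReceptorState.from_dict({"NOT_A_SPECIES": 1.0})


class TestSteadyState:
    def test_resting_bcr_balances_synthesis_and_decay(self, receptor_rest):
        # with no ligand, d[BCR]/dt = phi2 - phi3*[BCR] = 0
        assert receptor_rest["BCR"] == pytest.approx(4.93 / 1.43, rel=1e-3)

    def test_resting_traf3_balances_synthesis_and_decay(self, receptor_rest):
        assert receptor_rest["TRAF3"] == pytest.approx(10.0 / 0.5, rel=1e-3)

    def test_self_consistency(self, receptor_params, receptor_rest):
        """Re-entering the steady state leaves residual derivatives tiny."""
        state, converged = find_steady_state(receptor_params,
                                             initial=receptor_rest.as_array())
        assert converged
        dy = receptor_rhs(state.as_array(), receptor_params)
        assert np.max(np.abs(dy) / (np.abs(state.as_array()) + 1.0)) < 1e-6


class TestSimulation:
    def test_zero_dose_protocol_stays_at_steady_state(self, receptor_params,
                                                      receptor_rest):
        traj = simulate_receptor(StimulationProtocol(), receptor_params,
                                 t_grid=np.linspace(0, 96, 25),
                                 initial_state=receptor_rest)
        rest = receptor_rest.as_array()
        drift = np.abs(traj.values - rest) / (np.abs(rest) + 1e-9)
        assert drift.max() < 1e-2

    def test_conservation_laws_hold_along_trajectory(self, receptor_params,
                                                     receptor_rest):
        proto = constant_stimulation(bcr_nM=0.25, cd40_nM=30.0)
        traj = simulate_receptor(proto, receptor_params,
                                 t_grid=np.linspace(0, 96, 97),
                                 initial_state=receptor_rest)
        start = conservation_totals(traj.values[0])
        for row in traj.values:
            now = conservation_totals(row)
            for pool, total0 in start.items():
                assert abs(now[pool] - total0) / total0 < 1e-4

    def test_cd40_step_gives_transient_ikk2_and_persistent_nik(
            self, receptor_params, receptor_rest):
        proto = constant_stimulation(cd40_nM=30.0)
        traj = simulate_receptor(proto, receptor_params,
                                 t_grid=np.linspace(0, 96, 193),
                                 initial_state=receptor_rest)
        ikk2 = traj.species("IKK2")
        nik = traj.species("NIK")
        t = traj.times
        i_peak = int(np.argmax(ikk2))
        assert 0 < t[i_peak] < 48  # IKK2 rises then declines
        assert ikk2[-1] < ikk2[i_peak]
        i24 = int(np.argmin(np.abs(t - 24.0)))
        assert nik[i24] > 3 * nik[0]  # non-canonical activity persists

    def test_antigen_pulse_ikk2_is_transient(self, receptor_params,
                                             receptor_rest):
        """A washed antigen pulse gives a canonical-kinase excursion that
        decays back toward baseline; the relaxation time is set by the CBM
        deactivation rate (0.126/h), so the return is essentially complete
        by 48 h and well underway at 24 h."""
        proto = StimulationProtocol(antigen=[LigandPulse(0.25, 0.0, 1.0)])
        traj = simulate_receptor(proto, receptor_params,
                                 t_grid=np.linspace(0, 48, 97),
                                 initial_state=receptor_rest)
        ikk2 = traj.species("IKK2")
        i24 = int(np.argmin(np.abs(traj.times - 24.0)))
        rest_level = ikk2[0]
        elevation = ikk2.max() - rest_level
        assert ikk2.max() > 2 * rest_level
        assert ikk2[i24] < rest_level + 0.7 * elevation   # declining at 24 h
        assert ikk2[-1] < rest_level + 0.15 * elevation   # near baseline at 48 h

    def test_receptor_engagement_monotone_in_dose(self, receptor_params,
                                                  receptor_rest):
        """Bound-receptor levels at fixed times increase with ligand dose on
        the survey dose ladders."""
        for species, doses, kind in [
                ("CD40LR", [0, 6, 12, 18, 30], "cd40"),
                ("ABCR", [0, 0.0005, 0.005, 0.05, 0.25], "bcr")]:
            levels = []
            for d in doses:
                proto = constant_stimulation(
                    bcr_nM=d if kind == "bcr" else 0.0,
                    cd40_nM=d if kind == "cd40" else 0.0)
                traj = simulate_receptor(proto, receptor_params,
                                         t_grid=np.array([0.0, 7.0]),
                                         initial_state=receptor_rest)
                levels.append(traj.species(species)[-1])
            assert all(b >= a for a, b in zip(levels, levels[1:]))

    def test_tolerance_refinement_changes_endpoint_little(self, receptor_params,
                                                          receptor_rest):
        proto = constant_stimulation(cd40_nM=30.0)
        kw = dict(t_grid=np.array([0.0, 96.0]), initial_state=receptor_rest)
        coarse = simulate_receptor(proto, receptor_params, atol=1e-5,
                                   rtol=1e-3, **kw)
        fine = simulate_receptor(proto, receptor_params, atol=5e-6,
                                 rtol=5e-4, **kw)
        rel = np.abs(coarse.values[-1] - fine.values[-1]) / (
            np.abs(fine.values[-1]) + 1e-8)
        # measured refinement shift is ~5e-3 on the slowest species
        assert rel.max() < 1e-2

    def test_negative_dose_is_rejected(self):
        proto = StimulationProtocol(cd40l=[LigandPulse(-1.0, 0.0)])
        with pytest.raises(ValueError):
            simulate_receptor(proto)


class TestRateTable:
    def test_roundtrip_matches_builtin_defaults(self, tmp_path):
        path = tmp_path / "rates.csv"
        write_rate_table(path)
        params = load_rate_table(path)
        np.testing.assert_array_equal(params.phi[1:], np.array(PHI_DEFAULTS)[1:])

    def test_loader_rejects_missing_rows(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("module,index,reaction,rate,units,source,category\n"
                        "BCR receptor,2,\"-> BCR\",4.93,nM h-1,Fitted,synthesis\n")
        with pytest.raises(ConfigurationError):
            load_rate_table(path)


def test_trajectory_tidy_export(receptor_params, receptor_rest):
    proto = constant_stimulation(cd40_nM=6.0)
    traj = simulate_receptor(proto, receptor_params,
                             t_grid=np.array([0.0, 24.0]),
                             initial_state=receptor_rest)
    df = traj.to_frame(cell_id="c1")
    assert set(df.columns) == {"time_h", "species", "concentration_nM", "cell_id"}
    assert len(df) == 2 * N_SPECIES
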