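"""FBA/FVA/MoMA and model-hygiene routines against independent oracles
(vertex enumeration, per-reaction LPs via cobrapy, grid search)."""

import numpy as np
import pytest

from fluxtarget.network import Reaction, to_cobra
from fluxtarget.solvers import (
    InfeasibleModelError,
    MetabolicTask,
    check_metabolic_task,
    fba,
    find_blocked_reactions,
    fva,
    leak_test,
    load_tasks,
    moma,
    remove_dead_ends,
)

from conftest import brute_force_fba, build_model


class TestFba:
    def test_chain_min_capacity(self, chain_model):
        assert fba(chain_model).objective_value == pytest.approx(10.0)

    def test_bottleneck(self, bottleneck_model):
        assert fba(bottleneck_model).objective_value == pytest.approx(3.0)

    def test_steady_state_and_bounds(self, template):
        sol = fba(template)
        S = template.stoichiometric_matrix()
        v = np.array([sol[r] for r in template.reaction_ids])
        assert np.max(np.abs(S @ v)) < 1e-7
        for rxn in template.reactions:
            assert rxn.lower_bound - 1e-7 <= sol[rxn.id] <= rxn.upper_bound + 1e-7

    def test_matches_vertex_enumeration(self, two_path_model, bottleneck_model):
        for model in (two_path_model, bottleneck_model):
            assert fba(model).objective_value == pytest.approx(
                brute_force_fba(model), abs=1e-6
            )

    def test_template_matches_cobra(self, template):
        sol = to_cobra(template).optimize()
        assert fba(template).objective_value == pytest.approx(
            sol.objective_value, abs=1e-6
        )

    def test_invariant_under_reaction_permutation(self, template):
        shuffled = template.copy()
        shuffled.reactions = list(reversed(shuffled.reactions))
        shuffled._index()
        assert fba(shuffled).objective_value == pytest.approx(
            fba(template).objective_value, abs=1e-8
        )

    def test_invariant_under_reversible_split(self, template):
        """Splitting a reversible reaction into two irreversibles preserves
        the optimum."""

        split = template.copy()
        rev = split.reaction("PGI")
        assert rev.lower_bound < 0
        fwd_ub, rev_ub = rev.upper_bound, -rev.lower_bound
        rev.lower_bound = 0.0
        rev.upper_bound = fwd_ub
        split.reactions.append(
            Reaction(
                id="PGI_rev",
                stoichiometry={m: -c for m, c in rev.stoichiometry.items()},
                lower_bound=0.0,
                upper_bound=rev_ub,
                gpr=rev.gpr,
            )
        )
        split._index()
        assert fba(split).objective_value == pytest.approx(
            fba(template).objective_value, abs=1e-8
        )

    def test_infeasible_reports_status(self, chain_model):
        model = chain_model.copy()
        model.reaction("R1").lower_bound = 11.0  # beyond uptake capacity
        model.reaction("R1").upper_bound = 12.0
        with pytest.raises(InfeasibleModelError) as err:
            fba(model)
        assert err.value.status


class TestFva:
    def test_bounds_bracket_fba_flux(self, template):
        sol = fba(template)
        res = fva(template, objective_fraction=1.0)
        for rxn_id, (lo, hi) in res.ranges.items():
            assert lo - 1e-6 <= sol[rxn_id] <= hi + 1e-6
            assert lo <= hi + 1e-9

    def test_range_narrows_with_fraction(self, two_path_model):
        wide = fva(two_path_model, objective_fraction=0.0)
        tight = fva(two_path_model, objective_fraction=1.0)
        assert wide.ranges["R1"][1] - wide.ranges["R1"][0] >= (
            tight.ranges["R1"][1] - tight.ranges["R1"][0] - 1e-9
        )
        # parallel path: each route alone spans [0, 10] at fraction 0
        assert wide.ranges["R1"] == pytest.approx((0.0, 10.0), abs=1e-6)

    def test_matches_cobra_fva(self, template):
        from cobra.flux_analysis import flux_variability_analysis

        res = fva(template, objective_fraction=0.9)
        ref = flux_variability_analysis(
            to_cobra(template), fraction_of_optimum=0.9, processes=1
        )
        for rxn_id, (lo, hi) in res.ranges.items():
            assert lo == pytest.approx(ref.loc[rxn_id, "minimum"], abs=1e-5)
            assert hi == pytest.approx(ref.loc[rxn_id, "maximum"], abs=1e-5)

    def test_dead_branch_is_zero(self):
        model = build_model(
            "dead",
            [
                ("EX_A", {"a_e": -1}, -10.0, 1000.0, ""),
                ("R1", {"a_e": -1, "b_c": 1}, 0.0, 10.0, ""),
                ("R2", {"b_c": -1}, 0.0, 10.0, ""),
                ("R3", {"x_c": -1, "y_c": 1}, 0.0, 10.0, ""),  # no producer of x
            ],
            "R2",
        )
        res = fva(model, objective_fraction=0.0)
        assert res.ranges["R3"] == pytest.approx((0.0, 0.0), abs=1e-9)


class TestBlocked:
    def test_no_producer_consumer_blocked(self):
        model = build_model(
            "b",
            [
                ("EX_A", {"a_e": -1}, -10.0, 1000.0, ""),
                ("R1", {"a_e": -1, "b_c": 1}, 0.0, 10.0, ""),
                ("R2", {"b_c": -1}, 0.0, 10.0, ""),
                ("R3", {"q_c": -1, "r_c": 1}, 0.0, 10.0, ""),
            ],
            "R2",
        )
        assert find_blocked_reactions(model) == {"R3"}

    def test_optimal_path_not_blocked(self, template):
        sol = fba(template)
        blocked = find_blocked_reactions(template)
        for rxn_id, flux in sol.fluxes.items():
            if abs(flux) > 1e-6:
                assert rxn_id not in blocked

    def test_matches_cobra(self, template):
        from cobra.flux_analysis import find_blocked_reactions as cobra_blocked

        assert find_blocked_reactions(template) == set(
            cobra_blocked(to_cobra(template), processes=1)
        )


class TestDeadEnds:
    def test_unconsumed_product_removed(self):
        model = build_model(
            "d",
            [
                ("EX_A", {"a_e": -1}, -10.0, 1000.0, ""),
                ("R1", {"a_e": -1, "b_c": 1}, 0.0, 10.0, ""),
                ("R2", {"b_c": -1}, 0.0, 10.0, ""),
                ("R3", {"a_e": -1, "x_c": 1}, 0.0, 10.0, ""),  # x never consumed
            ],
            "R2",
        )
        pruned, log = remove_dead_ends(model)
        assert "R3" not in pruned.reaction_ids
        assert any(entry["metabolite"] == "x_c" for entry in log)

    def test_connected_cycle_untouched(self, two_path_model):
        pruned, log = remove_dead_ends(two_path_model)
        assert pruned.reaction_ids == two_path_model.reaction_ids
        assert log == []

    def test_fixpoint_order_independent(self, template):
        """The fixpoint is the same regardless of metabolite scan order."""

        base, _ = remove_dead_ends(template)
        shuffled = template.copy()
        shuffled.metabolites = list(reversed(shuffled.metabolites))
        shuffled.reactions = list(reversed(shuffled.reactions))
        shuffled._index()
        alt, _ = remove_dead_ends(shuffled)
        assert set(alt.reaction_ids) == set(base.reaction_ids)

    def test_no_dead_metabolite_in_output(self, template):
        pruned, _ = remove_dead_ends(template)
        from fluxtarget.solvers import _producers_consumers

        producers, consumers = _producers_consumers(pruned)
        for met in pruned.metabolites:
            assert producers[met.id] and consumers[met.id]

    def test_objective_protected(self):
        model = build_model(
            "obj",
            [("ONLY", {"a_c": 1}, 0.0, 10.0, "")],
            "ONLY",
        )
        with pytest.raises(RuntimeError, match="objective"):
            remove_dead_ends(model)


class TestLeak:
    def test_balanced_template_clean(self, template):
        assert leak_test(template) == []

    def test_planted_imbalance_detected(self, template):
        """An internal mass-creating cycle (pyruvate recycled to hexose while
        glycolysis doubles it) leaks even with every exchange closed."""

        leaky = template.copy()
        leaky.reactions.append(
            Reaction(id="MAGIC", stoichiometry={"pyr_c": -1.0, "g6p_c": 1.0},
                     lower_bound=0.0, upper_bound=1000.0)
        )
        leaky._index()
        leaks = leak_test(leaky)
        assert leaks  # the imbalance is detected
        assert "nrg_c" in leaks  # net energy created per cycle turn
        # nothing in the cycle produces free glucose or leucine
        assert "glc_c" not in leaks
        assert "leu_c" not in leaks


class TestMoma:
    def test_identity_without_perturbation(self, template):
        wt = fba(template)
        again = moma(template, wt)
        for rxn_id, flux in wt.fluxes.items():
            assert again[rxn_id] == pytest.approx(flux, abs=1e-5)

    @pytest.mark.parametrize("variant", ["quadratic", "linear"])
    def test_sole_path_knockout_zero_growth(self, chain_model, variant):
        wt = fba(chain_model)
        perturbed = chain_model.copy()
        perturbed.reaction("R1").lower_bound = 0.0
        perturbed.reaction("R1").upper_bound = 0.0
        res = moma(perturbed, wt, variant=variant)
        assert res.objective_value == pytest.approx(0.0, abs=1e-6)

    def test_quadratic_matches_grid_search(self, two_path_model):
        """After knocking out one of two parallel routes the feasible set is
        a one-parameter family; dense grid search over it is the oracle."""

        wt = fba(two_path_model)
        perturbed = two_path_model.copy()
        perturbed.reaction("R1").lower_bound = 0.0
        perturbed.reaction("R1").upper_bound = 0.0
        res = moma(perturbed, wt)
        # family: R2 = R3 = t, EX_A = -t, R1 = 0 for t in [0, 10]
        t = np.linspace(0.0, 10.0, 200001)
        dist = (
            (0.0 - wt["R1"]) ** 2
            + (t - wt["R2"]) ** 2
            + (t - wt["R3"]) ** 2
            + (-t - wt["EX_A"]) ** 2
        )
        t_star = t[np.argmin(dist)]
        assert res["R2"] == pytest.approx(t_star, abs=1e-4)
        assert res["R3"] == pytest.approx(t_star, abs=1e-4)
        d_res = sum(
            (res[r] - wt[r]) ** 2 for r in two_path_model.reaction_ids
        )
        assert d_res == pytest.approx(dist.min(), abs=1e-4)

    def test_distance_zero_iff_wt_feasible(self, two_path_model):
        wt = fba(two_path_model)
        perturbed = two_path_model.copy()
        perturbed.reaction("R3").upper_bound = wt["R3"] / 2
        res = moma(perturbed, wt)
        dist = sum((res[r] - wt[r]) ** 2 for r in two_path_model.reaction_ids)
        assert dist > 1e-3  # wt infeasible -> strictly positive adjustment

    def test_unknown_variant_rejected(self, chain_model):
        with pytest.raises(ValueError):
            moma(chain_model, fba(chain_model), variant="cubic")


class TestTasks:
    def test_glucose_to_pyruvate_passes(self, template):
        # pyruvate synthesis co-produces energy, so the task names both sinks
        task = MetabolicTask(id="t1", inputs={"glc_e": 10.0},
                             outputs={"pyr_c", "nrg_c"})
        assert check_metabolic_task(template, task) is True

    def test_unreachable_output_fails(self, template):
        # lipid needs energy input beyond glucose-free media
        task = MetabolicTask(id="t2", inputs={"leu_e": 1.0},
                             outputs={"pyr_c"})
        assert check_metabolic_task(template, task) is False

    def test_unknown_metabolite_is_error(self, template):
        task = MetabolicTask(id="t3", inputs={"nope_c": 1.0}, outputs={"pyr_c"})
        with pytest.raises(KeyError):
            check_metabolic_task(template, task)

    def test_matches_feasibility_oracle(self, template):
        """Pass/fail equals a per-output feasibility probe done by brute
        force on an equivalent explicitly-modified model."""

        cases = [
            ({"glc_e": 5.0}, {"lac_e"}),
            ({"glc_e": 5.0}, {"lipid_c"}),
            ({"gln_e": 5.0}, {"akg_m"}),
            ({"gln_e": 5.0}, {"g6p_c"}),
        ]
        for inputs, outputs in cases:
            work = template.copy()
            for rxn in work.reactions:
                if rxn.is_exchange:
                    rxn.lower_bound = rxn.upper_bound = 0.0
            expected = True
            for out_met in outputs:
                probe = work.copy()
                probe.metabolites = list(probe.metabolites)
                for met_id, rate in inputs.items():
                    probe.reactions.append(
                        Reaction(id=f"SUPPLY_{met_id}",
                                 stoichiometry={met_id: 1.0},
                                 lower_bound=0.0, upper_bound=rate)
                    )
                probe.reactions.append(
                    Reaction(id="SINK", stoichiometry={out_met: -1.0},
                             lower_bound=0.0, upper_bound=1000.0)
                )
                probe.objective_reaction = "SINK"
                probe._index()
                if fba(probe).objective_value <= 1e-6:
                    expected = False
            task = MetabolicTask(id="x", inputs=inputs, outputs=outputs)
            assert check_metabolic_task(template, task) is expected

    def test_task_tsv_roundtrip(self, tmp_path):
        path = tmp_path / "tasks.tsv"
        path.write_text(
            "task_id\tinputs\toutputs\texpected\n"
            "t1\tglc_e:10;gln_e:1\tpyr_c;lac_c\tpass\n"
            "t2\t\takg_m\tfail\n"
        )
        tasks = load_tasks(path)
        assert tasks[0].inputs == {"glc_e": 10.0, "gln_e": 1.0}
        assert tasks[0].outputs == {"pyr_c", "lac_c"}
        assert tasks[1].expected == "fail"
        assert tasks[1].inputs == {}
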