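"""Structure, matrix assembly, validation and serialization of the network."""

import dataclasses
import json

import numpy as np
import pytest

from acetoflux import (
    ModelError,
    ModelParseError,
    ModelStructureError,
    build_reference_network,
    build_stoichiometric_matrix,
    read_model,
    validate_network,
    write_model,
)
from acetoflux.network import model_from_dict, model_to_dict


class TestReferenceModel:
    def test_determined_system_shape(self, reconciled_model):
        """33 flux variables constrained by 33 equations."""
        assert reconciled_model.n_fluxes == 33
        assert len(reconciled_model.equations) == 33
        assert reconciled_model.flux_names[0] == "p1"
        assert reconciled_model.biomass_flux == "p33"

    def test_enzymatic_catalog_has_22_reactions(self, reconciled_model):
        enzymatic = [r for r in reconciled_model.reactions if r.kind == "enzymatic"]
        assert len(enzymatic) == 22

    def test_nine_biomass_drains(self, reconciled_model):
        pools = {d.pool for d in reconciled_model.drains}
        assert pools == {"G6P", "F6P", "Ru5P", "G3P", "PEP", "Pyr", "AcCoA",
                         "OAA", "aKet"}

    @pytest.mark.parametrize(
        "pool, coefficient",
        [
            ("G6P", 0.005349),
            ("F6P", 0.001644),
            ("Ru5P", 0.008948),
            ("G3P", 0.001291),
            ("PEP", 0.006889),
            ("Pyr", 0.03604),
            ("AcCoA", 0.004139),
            ("OAA", 0.01959),
            ("aKet", 0.002744),
        ],
    )
    def test_as_printed_drain_coefficients(self, as_printed_model, pool, coefficient):
        assert as_printed_model.coefficients[pool] == pytest.approx(coefficient)

    def test_reconciled_differs_only_in_pyr_and_oaa(
        self, reconciled_model, as_printed_model
    ):
        for pool in ("G6P", "F6P", "Ru5P", "G3P", "PEP", "AcCoA", "aKet"):
            assert reconciled_model.coefficients[pool] == (
                as_printed_model.coefficients[pool]
            )
        assert reconciled_model.coefficients["Pyr"] == pytest.approx(0.008571)
        assert reconciled_model.coefficients["OAA"] == pytest.approx(0.001904)

    def test_pep_balance_uses_pep_drain_p28(self, reconciled_model):
        """The PEP balance row must drain through p28, the PEP drain (the
        listing's p29 belongs to the pyruvate pool)."""
        eq7 = next(e for e in reconciled_model.equations if e.row == 7)
        assert eq7.terms == {"p7": 1.0, "p8": -1.0, "p9": -1.0, "p28": -1.0}

    def test_ru5p_f6p_drain_index_assignment(self, reconciled_model):
        assert reconciled_model.drain_for_pool("Ru5P").flux == "p25"
        assert reconciled_model.drain_for_pool("F6P").flux == "p26"

    def test_unknown_coefficient_set_rejected(self):
        with pytest.raises(ModelError, match="unknown coefficient set"):
            build_reference_network("bogus")

    def test_build_is_idempotent(self):
        assert build_reference_network("reconciled") is build_reference_network(
            "reconciled"
        )

    def test_balanced_metabolites_have_producer_and_consumer(self, reconciled_model):
        balances = {e.label: e for e in reconciled_model.balance_equations
                    if e.kind == "balance"}
        for met in reconciled_model.metabolites:
            if met.balanced:
                signs = {np.sign(c) for c in balances[met.id].terms.values()}
                assert signs == {1.0, -1.0}, met.id


class TestMatrix:
    def test_shape_and_labels(self, reconciled_model):
        labeled = build_stoichiometric_matrix(reconciled_model)
        assert labeled.shape == (33, 33)
        assert labeled.column_labels == tuple(f"p{i}" for i in range(1, 34))
        assert [int(r.split(":")[0]) for r in labeled.row_labels] == list(
            range(1, 34)
        )

    def test_branch_ratio_row_entries(self, reconciled_model):
        """The PEP branch ratio row is +1 at p8 and -6 at p9, zero elsewhere."""
        labeled = build_stoichiometric_matrix(reconciled_model)
        row = labeled.matrix[7]  # published row 8
        assert row[7] == 1.0 and row[8] == -6.0
        assert np.count_nonzero(row) == 2

    def test_written_factors_enter_verbatim(self, reconciled_model):
        labeled = build_stoichiometric_matrix(reconciled_model)
        A = labeled.matrix
        assert A[4, 4] == -0.5   # row 5: p4 - 0.5 p5
        assert A[5, 6] == -0.5   # row 6: ... - 0.5 p7
        assert A[9, 11] == 4.0   # row 10: 4 p12 - p13

    def test_no_unconstrained_flux(self, reconciled_model):
        labeled = build_stoichiometric_matrix(reconciled_model)
        assert np.all(np.any(labeled.matrix != 0.0, axis=0))

    def test_unknown_flux_symbol_is_structural_error(self, reconciled_model):
        eq = reconciled_model.balance_equations[0]
        broken = dataclasses.replace(
            reconciled_model,
            balance_equations=(
                dataclasses.replace(eq, terms={**eq.terms, "p99": 1.0}),
            ) + reconciled_model.balance_equations[1:],
        )
        with pytest.raises(ModelStructureError, match="p99"):
            build_stoichiometric_matrix(broken)


class TestValidation:
    def test_reference_model_is_full_rank(self, reconciled_model):
        report = validate_network(reconciled_model)
        assert report.square
        assert report.full_rank and report.rank == 33
        assert np.isfinite(report.condition_number)
        assert report.orphan_fluxes == ()
        assert report.unbalanced_pools == ()
        assert report.ok

    def test_deleting_an_equation_flags_underdetermination(self, reconciled_model):
        truncated = dataclasses.replace(
            reconciled_model,
            exchange_equations=tuple(
                e for e in reconciled_model.exchange_equations if e.row != 32
            ),
        )
        report = validate_network(truncated)
        assert not report.square
        assert report.rank == 32
        assert not report.ok

    def test_duplicated_flux_column_flags_rank_deficiency(self):
        # tiny 3-flux model where p3 duplicates p2 in every equation
        payload = {
            "n_fluxes": 3,
            "metabolites": [{"id": "A", "balanced": True},
                            {"id": "X", "balanced": False}],
            "balance_equations": [
                {"row": 1, "label": "A", "kind": "balance",
                 "terms": {"p1": "1", "p2": "-1", "p3": "-1"}},
                {"row": 2, "label": "A branch ratio", "kind": "ratio",
                 "terms": {"p2": "1", "p3": "1"}},
            ],
            "drains": [],
            "coefficient_sets": {"default": {}},
            "exchanges": [
                {"row": 3, "rate": "glc_uptake", "terms": {"p1": "1", "p3": "0"}},
            ],
        }
        report = validate_network(model_from_dict(payload))
        assert report.square
        assert report.rank == 2
        assert not report.full_rank


class TestSerialization:
    def test_round_trip_is_lossless(self, reconciled_model, tmp_path):
        path = tmp_path / "model.json"
        write_model(reconciled_model, path)
        again = read_model(path)
        assert model_to_dict(again) == model_to_dict(reconciled_model)
        assert again.equations == reconciled_model.equations

    def test_malformed_coefficient_reports_location(self, reconciled_model, tmp_path):
        payload = model_to_dict(reconciled_model)
        payload["balance_equations"][3]["terms"]["p4"] = "abc"
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(payload))
        with pytest.raises(ModelParseError, match=r"row 4.*'p4'.*'abc'"):
            read_model(path)

    def test_missing_biomass_flux_is_structural_error(
        self, reconciled_model, tmp_path
    ):
        payload = model_to_dict(reconciled_model)
        payload["exchanges"] = [e for e in payload["exchanges"]
                                if e["rate"] != "biomass_rate"]
        for eq in payload["balance_equations"]:
            eq["terms"].pop("p33", None)
        payload["drains"] = []
        path = tmp_path / "nobm.json"
        path.write_text(json.dumps(payload))
        with pytest.raises(ModelStructureError, match="biomass flux missing"):
            read_model(path)

    def test_unknown_pool_in_drain_is_named(self, reconciled_model, tmp_path):
        payload = model_to_dict(reconciled_model)
        payload["drains"][0]["pool"] = "XYZ"
        path = tmp_path / "badpool.json"
        path.write_text(json.dumps(payload))
        with pytest.raises(ModelStructureError, match="XYZ"):
            read_model(path)

    def test_invalid_json_reports_line(self, tmp_path):
        path = tmp_path / "broken.json"
        path.write_text('{\n "n_fluxes": 3,,\n}')
        with pytest.raises(ModelParseError, match="line 2"):
            read_model(path)
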