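"""Grantham scoring, conservation calls and rule-based classification."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitomct import (
    CodingEffect,
    CriterionFlags,
    EvidenceRecord,
    Rule,
    DEFAULT_RULE,
    classify,
    conservation_call,
    evaluate_criteria,
    grantham_distance,
)
from mitomct.pathogenicity import ConfigError, GranthamTable

# Frozen oracle: the 1974 distance formula
# D = rho * sqrt(alpha*dc^2 + beta*dp^2 + gamma*dv^2) evaluated with the
# published composition/polarity/volume values and rho normalising the
# mean pair distance to 100, rounded to integers.  Computed by a
# standalone script before the implementation and spot-checked against
# well-known published distances (A-T 58, Y-H 83, W-C 215, L-I 5).
GRANTHAM_190 = {
"AC": 195, "AD": 126, "AE": 107, "AF": 113, "AG": 60,
"AH": 86, "AI": 94, "AK": 106, "AL": 96, "AM": 85,
"AN": 111, "AP": 27, "AQ": 91, "AR": 111, "AS": 99,
"AT": 58, "AV": 65, "AW": 148, "AY": 112, "CD": 154,
"CE": 170, "CF": 205, "CG": 158, "CH": 174, "CI": 198,
"CK": 202, "CL": 198, "CM": 196, "CN": 139, "CP": 169,
"CQ": 154, "CR": 180, "CS": 112, "CT": 149, "CV": 191,
"CW": 215, "CY": 194, "DE": 45, "DF": 177, "DG": 94,
"DH": 81, "DI": 168, "DK": 102, "DL": 172, "DM": 160,
"DN": 23, "DP": 108, "DQ": 61, "DR": 96, "DS": 66,
"DT": 85, "DV": 152, "DW": 191, "DY": 160, "EF": 140,
"EG": 98, "EH": 41, "EI": 134, "EK": 57, "EL": 139,
"EM": 126, "EN": 41, "EP": 94, "EQ": 29, "ER": 54,
"ES": 80, "ET": 66, "EV": 121, "EW": 152, "EY": 123,
"FG": 153, "FH": 100, "FI": 21, "FK": 102, "FL": 22,
"FM": 29, "FN": 158, "FP": 114, "FQ": 116, "FR": 97,
"FS": 155, "FT": 103, "FV": 50, "FW": 40, "FY": 22,
"GH": 98, "GI": 136, "GK": 127, "GL": 138, "GM": 127,
"GN": 79, "GP": 42, "GQ": 87, "GR": 125, "GS": 55,
"GT": 59, "GV": 109, "GW": 184, "GY": 147, "HI": 94,
"HK": 32, "HL": 99, "HM": 86, "HN": 68, "HP": 76,
"HQ": 24, "HR": 29, "HS": 89, "HT": 47, "HV": 84,
"HW": 115, "HY": 83, "IK": 102, "IL": 5, "IM": 10,
"IN": 149, "IP": 96, "IQ": 109, "IR": 98, "IS": 142,
"IT": 89, "IV": 30, "IW": 61, "IY": 33, "KL": 106,
"KM": 95, "KN": 94, "KP": 103, "KQ": 53, "KR": 26,
"KS": 121, "KT": 78, "KV": 97, "KW": 110, "KY": 85,
"LM": 14, "LN": 153, "LP": 98, "LQ": 113, "LR": 102,
"LS": 144, "LT": 92, "LV": 32, "LW": 61, "LY": 36,
"MN": 141, "MP": 87, "MQ": 101, "MR": 92, "MS": 135,
"MT": 81, "MV": 22, "MW": 67, "MY": 35, "NP": 90,
"NQ": 46, "NR": 85, "NS": 46, "NT": 65, "NV": 133,
"NW": 174, "NY": 142, "PQ": 75, "PR": 103, "PS": 73,
"PT": 38, "PV": 68, "PW": 147, "PY": 110, "QR": 43,
"QS": 68, "QT": 41, "QV": 96, "QW": 130, "QY": 99,
"RS": 109, "RT": 71, "RV": 96, "RW": 101, "RY": 77,
"ST": 58, "SV": 123, "SW": 177, "SY": 143, "TV": 70,
"TW": 128, "TY": 92, "VW": 88, "VY": 55, "WY": 37,
}


class TestGranthamTable:
    def test_matches_frozen_formula_oracle_on_all_190_pairs(self):
        for pair, expected in GRANTHAM_190.items():
            assert grantham_distance(pair[0], pair[1]) == expected, pair

    def test_symmetry_and_zero_diagonal(self):
        aas = "ARNDCQEGHILKMFPSTWYV"
        for a, b in itertools.combinations(aas, 2):
            assert grantham_distance(a, b) == grantham_distance(b, a)
        for a in aas:
            assert grantham_distance(a, a) == 0

    def test_known_extremes(self):
        assert grantham_distance("L", "I") == 5   # most similar pair
        assert grantham_distance("C", "W") == 215  # most dissimilar pair

    def test_nonstandard_residue_rejected(self):
        with pytest.raises(ValueError):
            grantham_distance("A", "*")
        with pytest.raises(ValueError):
            grantham_distance("B", "A")

    def test_rho_normalises_mean_to_100(self):
        table = GranthamTable()
        raws = [table._raw(a, b) for a, b in itertools.combinations(sorted(table.properties), 2)]
        assert sum(raws) / len(raws) * table.rho == pytest.approx(100.0)


class TestConservation:
    def test_unanimous_column_is_conserved(self):
        col = {f"sp{i}": "A" for i in range(8)}
        assert conservation_call(col, "sp0") is True

    def test_one_divergent_species_breaks_strict_identity(self):
        col = {f"sp{i}": "A" for i in range(7)}
        col["sp7"] = "S"
        assert conservation_call(col, "sp0", min_identity=1.0) is False
        # 7/8 = 0.875 >= 0.8
        assert conservation_call(col, "sp0", min_identity=0.8) is True

    def test_gap_only_column_is_indeterminate(self):
        col = {"a": "-", "b": "-"}
        assert conservation_call(col, "a") is None

    def test_missing_reference_species_rejected(self):
        with pytest.raises(ValueError, match="reference species"):
            conservation_call({"a": "A", "b": "A"}, "zebra")

    def test_column_from_msa_fasta(self):
        import io

        from mitomct.pathogenicity import alignment_column

        msa = ">human\nMA-T\n>mouse\nMAST\n>frog\nMA-T\n"
        col = alignment_column(io.StringIO(msa), 2)
        assert col == {"human": "A", "mouse": "A", "frog": "A"}
        assert conservation_call(col, "human") is True
        gappy = alignment_column(io.StringIO(msa), 3)
        assert conservation_call(gappy, "human") is None


MISSENSE_AT = CodingEffect("ND5", 458, "A", "T", "missense")
MISSENSE_YH = CodingEffect("ND1", 304, "Y", "H", "missense")
NONSENSE = CodingEffect("ND5", 159, "Y", "*", "nonsense")


class TestEvaluateCriteria:
    def test_grantham_computed_from_residue_pair(self):
        flags = evaluate_criteria(MISSENSE_AT, EvidenceRecord())
        assert flags.grantham is True  # 58 > 50
        assert flags.mutpred is None
        assert flags.protein_truncating is False

    def test_thresholds_are_strict_inequalities(self):
        at_threshold = evaluate_criteria(MISSENSE_AT, EvidenceRecord(mutpred=0.70))
        assert at_threshold.mutpred is False
        above = evaluate_criteria(MISSENSE_AT, EvidenceRecord(mutpred=0.783))
        assert above.mutpred is True
        # Grantham exactly 50 would not qualify either
        table_50 = evaluate_criteria(MISSENSE_AT, EvidenceRecord(grantham=50))
        assert table_50.grantham is False

    def test_full_evidence_record(self):
        ev = EvidenceRecord(conformational_change=True, disease_associated=True,
                            mtros_overproduction=True)
        flags = evaluate_criteria(MISSENSE_AT, ev)
        assert flags.met() == ["grantham", "conformational_change", "disease_associated",
                               "mtros_overproduction"]

    def test_truncating_effects_bypass_missense_criteria(self):
        flags = evaluate_criteria(NONSENSE, EvidenceRecord())
        assert flags.protein_truncating is True
        assert flags.grantham is None

    def test_mutpred_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            EvidenceRecord(mutpred=1.2)


class TestClassify:
    def test_conformational_route(self):
        # high Grantham + predicted conformational change
        flags = evaluate_criteria(
            MISSENSE_AT, EvidenceRecord(conformational_change=True, disease_associated=True,
                                        mtros_overproduction=True)
        )
        assert classify(flags).verdict == "predicted_pathogenic"

    def test_mutpred_route(self):
        flags = evaluate_criteria(
            MISSENSE_AT, EvidenceRecord(mutpred_high=True, conserved=True,
                                        mtros_overproduction=True)
        )
        assert classify(flags).verdict == "predicted_pathogenic"

    def test_high_grantham_alone_is_not_enough(self):
        # disease association without conformational or MutPred support
        flags = evaluate_criteria(
            MISSENSE_YH, EvidenceRecord(mutpred_high=False, disease_associated=True)
        )
        call = classify(flags)
        assert call.verdict == "not_predicted"
        assert "grantham" in call.criteria_met

    def test_truncating_is_pathogenic_under_default_rule(self):
        flags = evaluate_criteria(NONSENSE, EvidenceRecord())
        assert classify(flags).verdict == "predicted_pathogenic"

    def test_all_false_is_not_predicted(self):
        flags = CriterionFlags(grantham=False, mutpred=False, conserved=False,
                               conformational_change=False, disease_associated=False,
                               mtros_overproduction=False)
        assert classify(flags).verdict == "not_predicted"

    def test_all_missing_is_indeterminate(self):
        flags = CriterionFlags()
        assert classify(flags).verdict == "indeterminate"

    def test_call_records_rule_and_criteria(self):
        flags = evaluate_criteria(MISSENSE_AT, EvidenceRecord(conformational_change=True))
        call = classify(flags)
        assert call.rule_id == "default"
        assert set(call.criteria_met) == {"grantham", "conformational_change"}

    def test_unknown_criterion_in_rule_rejected(self):
        with pytest.raises(ConfigError, match="unknown criteria"):
            Rule("grantham and phlogiston")

    def test_custom_rule_is_honoured(self):
        rule = Rule("conserved and disease_associated", rule_id="strict")
        flags = CriterionFlags(conserved=True, disease_associated=True)
        call = classify(flags, rule)
        assert call.verdict == "predicted_pathogenic" and call.rule_id == "strict"

    TRI = st.sampled_from([True, False, None])

    @given(grantham=TRI, mutpred=TRI, conf=TRI, truncating=st.booleans(),
           upgrade=st.sampled_from(["grantham", "mutpred", "conformational_change"]))
    @settings(max_examples=200, deadline=None)
    def test_default_rule_is_monotone(self, grantham, mutpred, conf, truncating, upgrade):
        """Satisfying one more criterion never revokes a pathogenic verdict."""
        base = CriterionFlags(grantham=grantham, mutpred=mutpred,
                              conformational_change=conf, protein_truncating=truncating)
        kwargs = dict(grantham=grantham, mutpred=mutpred, conformational_change=conf)
        kwargs[upgrade] = True
        upgraded = CriterionFlags(protein_truncating=truncating, **kwargs)
        if classify(base).verdict == "predicted_pathogenic":
            assert classify(upgraded).verdict == "predicted_pathogenic"
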