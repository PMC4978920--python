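"""Z-scoring, threshold hit calling, classification and validation."""

import math
import statistics

import numpy as np
import pandas as pd
import pytest

from p53screen import (
    COLUMN_LABELS,
    call_hits,
    classify_regulators,
    compute_zscores,
    flag_low_expression,
    simulate_screen,
    validate_secondary,
    SimulationConfig,
)
from p53screen.errors import DegenerateConditionError
from p53screen.hit_calling import HitCall

from conftest import make_matrix


def _hit(gene, readout, treatment, z, threshold=2.0):
    direction = "positive_regulator" if z < 0 else "negative_regulator"
    return HitCall(gene, readout, treatment, z, direction, threshold)


# -- z-scores -----------------------------------------------------------------


def test_two_value_column_closed_form():
    m = make_matrix([[0.0] * 6, [2.0] * 6])
    zt = compute_zscores(m)
    # sample SD of {0, 2} is sqrt(2); z = (0-1)/sqrt(2), (2-1)/sqrt(2)
    assert zt.theta.iloc[0] == pytest.approx(math.sqrt(2))
    np.testing.assert_allclose(zt.z.iloc[:, 0], [-0.7071067811865475, 0.7071067811865475])


def test_constant_column_is_degenerate():
    with pytest.raises(DegenerateConditionError):
        compute_zscores(make_matrix([[1.0] * 6] * 5))


def test_zscores_standardize_lognormal_values(rng):
    m = make_matrix(np.exp(rng.normal(0, 0.4, size=(200, 6))))
    zt = compute_zscores(m)
    for col in COLUMN_LABELS:
        assert zt.z[col].mean() == pytest.approx(0.0, abs=1e-9)
        assert zt.z[col].std(ddof=1) == pytest.approx(1.0, abs=1e-9)


def test_controls_excluded_from_population_but_scored(rng):
    values = np.exp(rng.normal(0, 0.2, size=(20, 6)))
    roles = ["library"] * 18 + ["nontargeting_control", "tp53_control"]
    m = make_matrix(values, roles=roles)
    zt = compute_zscores(m)
    assert (zt.n_used == 18).all()
    lib = m.values.iloc[:18, 0]
    expected_mu = lib.mean()
    assert zt.mu.iloc[0] == pytest.approx(expected_mu)
    # control wells still receive z-scores against the library statistics
    assert not zt.z.iloc[18:].isna().any().any()
    zt_all = compute_zscores(m, include_controls=True)
    assert (zt_all.n_used == 20).all()


def test_missing_values_excluded_and_stay_missing(rng):
    values = np.exp(rng.normal(0, 0.2, size=(10, 6)))
    values[3, 0] = np.nan
    zt = compute_zscores(make_matrix(values))
    assert zt.n_used.iloc[0] == 9
    assert math.isnan(zt.z.iloc[3, 0])


# -- hit calling --------------------------------------------------------------


def test_boundary_value_is_not_a_hit():
    """z exactly at the threshold sits inside the non-hit window."""
    z = pd.DataFrame(
        [[2.0, -2.0, 0.0, 0.0, 0.0, 0.0]], index=["A"], columns=list(COLUMN_LABELS)
    )
    zt = compute_zscores(make_matrix(np.exp(np.random.default_rng(0).normal(0, 0.2, (5, 6)))))
    zt.z = z
    assert call_hits(zt, threshold=2.0) == []


def test_direction_follows_sign():
    zt = compute_zscores(make_matrix(np.exp(np.random.default_rng(0).normal(0, 0.2, (5, 6)))))
    zt.z = pd.DataFrame(
        [[-2.5, 2.2, 0.0, 0.0, 0.0, 0.0]], index=["A"], columns=list(COLUMN_LABELS)
    )
    hits = call_hits(zt)
    assert {(h.condition, h.direction) for h in hits} == {
        ("CDKN1A:DMSO", "positive_regulator"),
        ("CDKN1A:etoposide", "negative_regulator"),
    }


def test_hits_match_brute_force_enumeration(rng):
    """Independent direct enumeration over all (gene, condition) pairs."""
    values = np.exp(rng.normal(0, 0.5, size=(20, 6)))
    m = make_matrix(values)
    zt = compute_zscores(m)
    hits = {(h.gene, h.condition) for h in call_hits(zt, threshold=1.5)}
    expected = set()
    for j, col in enumerate(COLUMN_LABELS):
        column = [values[i, j] for i in range(20)]
        mu = statistics.fmean(column)
        sd = statistics.stdev(column)  # sample SD
        for i, gene in enumerate(m.genes):
            z = (values[i, j] - mu) / sd
            if abs(z) > 1.5:
                expected.add((gene, col))
    assert hits == expected


def test_hit_calls_invariant_under_affine_rescaling(rng):
    values = np.exp(rng.normal(0, 0.3, size=(50, 6)))
    m1 = make_matrix(values)
    scaled = values * 7.3 + 0.11  # positive affine map per condition
    m2 = make_matrix(scaled)
    key = lambda hits: {(h.gene, h.condition, h.direction) for h in hits}
    h1 = key(call_hits(compute_zscores(m1)))
    h2 = key(call_hits(compute_zscores(m2)))
    assert h1 == h2


def test_lowering_threshold_never_removes_hits(rng):
    m = make_matrix(np.exp(rng.normal(0, 0.3, size=(80, 6))))
    zt = compute_zscores(m)
    key = lambda hits: {(h.gene, h.condition) for h in hits}
    loose, strict = key(call_hits(zt, 1.0)), key(call_hits(zt, 2.0))
    assert strict <= loose


def test_tp53_like_profile_hits_all_six_conditions():
    """A strong knockdown of all readouts in both treatments scores everywhere."""
    m, _ = simulate_screen(SimulationConfig(n_genes=200, seed=11))
    hits = [h for h in call_hits(compute_zscores(m)) if h.gene == "TP53"]
    assert len(hits) == 6
    assert all(h.direction == "positive_regulator" for h in hits)


# -- classification -----------------------------------------------------------


def test_joint_positive_regulator_in_dmso():
    cls = classify_regulators(
        [_hit("SETD3", "CDKN1A", "DMSO", -2.6), _hit("SETD3", "BBC3", "DMSO", -2.2)]
    )
    gc = cls.genes["SETD3"]
    assert gc.category == "joint"
    assert gc.joint_detail == {"DMSO": "positive_regulator"}


def test_single_readout_hit_is_specific():
    cls = classify_regulators([_hit("X", "CDKN1A", "etoposide", 2.3)])
    gc = cls.genes["X"]
    assert gc.categories == {"CDKN1A_specific"}
    assert gc.hits[("CDKN1A", "etoposide")].direction == "negative_regulator"


def test_no_hits_means_no_classified_genes():
    assert classify_regulators([]).genes == {}


def test_gene_can_be_joint_and_tp53_regulator():
    """A PLK1-like profile: joint CDKN1A/BBC3 plus a TP53 hit."""
    cls = classify_regulators(
        [
            _hit("PLK1", "CDKN1A", "etoposide", -2.8),
            _hit("PLK1", "BBC3", "etoposide", -2.5),
            _hit("PLK1", "TP53", "etoposide", -2.1),
        ]
    )
    gc = cls.genes["PLK1"]
    assert {"joint", "TP53_specific"} <= gc.categories
    # joint takes precedence over readout-specific labels in the same treatment
    assert "CDKN1A_specific" not in gc.categories
    assert "BBC3_specific" not in gc.categories


def test_opposite_direction_pair_is_not_joint():
    cls = classify_regulators(
        [_hit("Y", "CDKN1A", "DMSO", -2.5), _hit("Y", "BBC3", "DMSO", 2.5)]
    )
    assert "joint" not in cls.genes["Y"].categories


def test_specific_rule_is_per_treatment():
    """Hit for CDKN1A in both treatments with no BBC3 partner stays specific."""
    cls = classify_regulators(
        [_hit("CBX7", "CDKN1A", "DMSO", -2.7), _hit("CBX7", "CDKN1A", "etoposide", -2.2)]
    )
    assert cls.genes["CBX7"].categories == {"CDKN1A_specific"}


# -- secondary validation -----------------------------------------------------


def _secondary_matrix(values_by_gene):
    """DMSO-only CDKN1A/BBC3 matrix from {gene: (cdkn1a, bbc3)}."""
    genes = list(values_by_gene)
    arr = np.full((len(genes), 6), np.nan)
    for i, g in enumerate(genes):
        arr[i, 0], arr[i, 2] = values_by_gene[g]
    return make_matrix(arr, genes=genes)


def test_flat_secondary_value_marks_false_positive(rng):
    pool = {f"N{i}": tuple(np.exp(rng.normal(0, 0.2, 2))) for i in range(30)}
    pool["HIT1"] = (0.3, 0.3)  # strongly down in the rescreen: confirmable
    pool["HIT2"] = (1.0, 1.0)  # exactly at the pool center: z ~ 0
    cls = classify_regulators(
        [
            _hit("HIT1", "CDKN1A", "DMSO", -2.4),
            _hit("HIT2", "CDKN1A", "DMSO", -2.8),
            _hit("ABSENT", "BBC3", "DMSO", -2.2),
        ]
    )
    cls = validate_secondary(cls, _secondary_matrix(pool), threshold=1.0)
    assert cls.genes["HIT1"].secondary_status == "confirmed"
    assert cls.genes["HIT2"].secondary_status == "not_confirmed"
    assert cls.genes["ABSENT"].secondary_status == "not_retested"


def test_direction_must_agree_unless_disabled(rng):
    pool = {f"N{i}": tuple(np.exp(rng.normal(0, 0.1, 2))) for i in range(30)}
    pool["G"] = (3.0, 1.0)  # strongly UP in the rescreen
    primary = [_hit("G", "CDKN1A", "DMSO", -2.5)]  # primary called it DOWN
    cls = validate_secondary(classify_regulators(primary), _secondary_matrix(pool))
    assert cls.genes["G"].secondary_status == "not_confirmed"
    cls2 = validate_secondary(
        classify_regulators(primary), _secondary_matrix(pool), require_direction=False
    )
    assert cls2.genes["G"].secondary_status == "confirmed"


def test_tp53_only_regulators_not_retested(rng):
    pool = {f"N{i}": tuple(np.exp(rng.normal(0, 0.2, 2))) for i in range(20)}
    pool["T"] = (0.2, 0.2)
    cls = classify_regulators([_hit("T", "TP53", "DMSO", -3.0)])
    cls = validate_secondary(cls, _secondary_matrix(pool))
    assert cls.genes["T"].secondary_status == "not_retested"


def test_empty_secondary_pool_warns_and_leaves_all_untouched():
    cls = classify_regulators([_hit("A", "CDKN1A", "DMSO", -2.5)])
    empty = make_matrix(np.empty((0, 6)), genes=[])
    with pytest.warns(UserWarning):
        cls = validate_secondary(cls, empty)
    assert cls.genes["A"].secondary_status == "not_retested"


# -- expression-based flagging ------------------------------------------------


def test_zero_expression_flagged_case_insensitively():
    cls = classify_regulators(
        [_hit("MBD3L1", "BBC3", "DMSO", -2.3), _hit("SFMBT1", "BBC3", "DMSO", -2.6)]
    )
    cls = flag_low_expression(cls, {"mbd3l1": 0.0, "SFMBT1": 3.7})
    assert cls.genes["MBD3L1"].low_expression_flag
    assert not cls.genes["SFMBT1"].low_expression_flag


def test_expression_flag_persists_alongside_secondary_confirmation(rng):
    """A gene can be secondary-confirmed and still flagged as not expressed."""
    pool = {f"N{i}": tuple(np.exp(rng.normal(0, 0.2, 2))) for i in range(30)}
    pool["DLX2"] = (4.0, 4.0)
    cls = classify_regulators([_hit("DLX2", "BBC3", "DMSO", 2.6)])
    cls = validate_secondary(cls, _secondary_matrix(pool))
    cls = flag_low_expression(cls, {"DLX2": 0.0})
    gc = cls.genes["DLX2"]
    assert gc.secondary_status == "confirmed" and gc.low_expression_flag


def test_genes_missing_from_expression_table_reported():
    cls = classify_regulators([_hit("NOVEL1", "CDKN1A", "DMSO", -2.5)])
    cls = flag_low_expression(cls, {"OTHER": 1.0})
    assert cls.missing_from_expression == ["NOVEL1"]
    assert not cls.genes["NOVEL1"].low_expression_flag
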