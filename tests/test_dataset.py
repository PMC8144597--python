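"""Dataset construction: truncation, labels, exclusions, litters,
standardization, G2+."""

from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pedsurv import SpeciesConfig
from pedsurv.dataset import (EXCLUDE_TOO_YOUNG, apply_exclusions,
                             assemble_offspring_table,
                             build_offspring_table, label_survival,
                             load_species_configs, make_replicates,
                             sample_one_per_litter,
                             standardize_within_species, subset_g2plus,
                             truncate_recent, PREDICTORS)
from pedsurv.pedigree import IndividualRecord, Pedigree, compute_metrics
from pedsurv.simulate import toy_configs, toy_fixtures


def _rec(iid, sire, dam, sex, birth, death=None, origin="captive",
         hybrid=False, species="toy", program="Europe"):
    return IndividualRecord(
        id=iid, sire_id=sire, dam_id=dam, sex=sex, birth_date=birth,
        death_date=death, birth_program=program, origin=origin,
        hybrid=hybrid, species=species)


# ---------------------------------------------------------------------------
# truncation
# ---------------------------------------------------------------------------

def test_truncate_drops_recent_births():
    ped = Pedigree([
        _rec("A", None, None, "female", date(2019, 9, 23), origin="wild"),
        _rec("B", None, None, "male", date(2018, 11, 27), origin="wild"),
        _rec("Z", None, None, "male", date(2020, 1, 1), origin="wild"),
    ])
    # current date 2020-01-01; cutoff 364 days earlier = 2019-01-02
    trunc, cutoff = truncate_recent(ped)
    assert cutoff == date(2019, 1, 2)
    assert "A" not in trunc          # born 100 days before current date
    assert "B" in trunc              # born 400 days before current date
    assert "Z" not in trunc


def test_truncate_empty_pedigree():
    trunc, _ = truncate_recent(Pedigree([]))
    assert len(trunc) == 0


# ---------------------------------------------------------------------------
# survival labels
# ---------------------------------------------------------------------------

CFG = SpeciesConfig("toy", maturity_female_days=365, maturity_male_days=365)
CFG_ASYM = SpeciesConfig("toy", maturity_female_days=456,
                         maturity_male_days=600)
CUTOFF = date(2019, 1, 3)


@pytest.mark.parametrize("sex, birth, death, cfg, expected", [
    # died at 200 d, maturity 365 -> did not survive
    ("female", date(2015, 1, 1), date(2015, 7, 20), CFG, 0),
    # alive, born 1000 d before cutoff -> survived
    ("male", date(2016, 4, 8), None, CFG, 1),
    # unknown sex uses the shorter maturity (456): died at 500 d -> survived
    ("unknown", date(2015, 1, 1), date(2016, 5, 15), CFG_ASYM, 1),
    # died beyond maturity -> survived
    ("female", date(2010, 1, 1), date(2012, 1, 1), CFG, 1),
    # born within the maturity window of the cutoff -> excluded even if
    # the death is already recorded
    ("female", date(2018, 6, 1), date(2018, 7, 1), CFG, EXCLUDE_TOO_YOUNG),
    ("male", date(2018, 6, 1), None, CFG, EXCLUDE_TOO_YOUNG),
])
def test_label_survival(sex, birth, death, cfg, expected):
    rec = _rec("X", None, None, sex, birth, death)
    assert label_survival(rec, cfg, CUTOFF) == expected


# ---------------------------------------------------------------------------
# exclusions
# ---------------------------------------------------------------------------

def test_exclusion_tally_forced_fixture():
    ped = toy_fixtures()["exclusions"]
    trunc, cutoff = truncate_recent(ped)
    excl = apply_exclusions(trunc, toy_configs(), cutoff)
    assert excl.tally == {"too_young": 1, "hybrid": 2,
                          "wild_or_released": 2, "unknown_parent": 1}
    assert sorted(excl.retained) == ["K1", "K2", "K3", "K4", "K5", "K6"]
    assert excl.survival["K3"] == 0  # died at 92 days
    assert excl.survival["K1"] == 1


def test_exclusions_idempotent():
    ped = toy_fixtures()["exclusions"]
    trunc, cutoff = truncate_recent(ped)
    first = apply_exclusions(trunc, toy_configs(), cutoff)
    second = apply_exclusions(trunc, toy_configs(), cutoff)
    assert first.retained == second.retained
    assert first.tally == second.tally
    # every retained record passes each filter on its own
    for iid in first.retained:
        rec = trunc[iid]
        assert not rec.hybrid and rec.origin == "captive"
        assert rec.sire_id is not None and rec.dam_id is not None
        assert label_survival(rec, toy_configs()[rec.species],
                              cutoff) in (0, 1)


def test_release_before_maturity_excluded():
    ped = Pedigree([
        _rec("P1", None, None, "male", date(2000, 1, 1), origin="wild"),
        _rec("P2", None, None, "female", date(2000, 1, 1), origin="wild",
             death=date(2020, 1, 1)),
        IndividualRecord(
            id="R1", sire_id="P1", dam_id="P2", sex="male",
            birth_date=date(2010, 1, 1), death_date=None,
            birth_program="Europe", origin="captive", hybrid=False,
            species="toy", release_date=date(2010, 6, 1)),
        _rec("K1", "P1", "P2", "female", date(2010, 1, 1)),
    ])
    trunc, cutoff = truncate_recent(ped)
    excl = apply_exclusions(trunc, toy_configs(), cutoff)
    assert "R1" not in excl.retained
    assert excl.tally["wild_or_released"] == 3  # P1, P2, R1
    assert excl.retained == ["K1"]


# ---------------------------------------------------------------------------
# table assembly and litters
# ---------------------------------------------------------------------------

def test_parental_age_and_litter_keys():
    ped = toy_fixtures()["litters_mixed"]
    metrics = compute_metrics(ped, ne=False)
    trunc, cutoff = truncate_recent(ped)
    excl = apply_exclusions(trunc, toy_configs(), cutoff)
    table = assemble_offspring_table(ped, metrics, excl, toy_configs())
    by_id = table.set_index("offspring_id")
    # date arithmetic: 1995-03-01 minus 1990-01-01 = 1885 days
    assert by_id.loc["L1", "dam_age"] == 1885.0
    # mammal litter: same dam, same day -> one key
    assert by_id.loc["L1", "litter_key"] == by_id.loc["L2", "litter_key"] \
        == by_id.loc["L3", "litter_key"]
    # clutch species: same dam, same year, different days -> one key
    assert by_id.loc["C1", "litter_key"] == by_id.loc["C2", "litter_key"]
    # but a different year is a different clutch
    assert by_id.loc["C3", "litter_key"] != by_id.loc["C1", "litter_key"]


def test_dam_age_worked_example():
    # offspring born 2000-01-01 to dam born 1995-01-01 -> 1826 days
    assert (date(2000, 1, 1) - date(1995, 1, 1)).days == 1826
    ped = Pedigree([
        _rec("S", None, None, "male", date(1995, 1, 1), origin="wild"),
        _rec("D", None, None, "female", date(1995, 1, 1), origin="wild"),
        _rec("O", "S", "D", "female", date(2000, 1, 1)),
        _rec("GUARD", None, None, "male", date(2002, 1, 1), origin="wild"),
    ])
    table, _ = build_offspring_table(ped, toy_configs())
    assert table.loc[table.offspring_id == "O", "dam_age"].item() == 1826.0


def test_nonpositive_parent_age_rejected():
    ped = Pedigree([
        _rec("S", None, None, "male", date(2000, 1, 1), origin="wild"),
        _rec("D", None, None, "female", date(2000, 1, 1), origin="wild"),
        _rec("O", "S", "D", "female", date(2000, 1, 1)),
        _rec("GUARD", None, None, "male", date(2004, 1, 1), origin="wild"),
    ])
    metrics = compute_metrics(ped, ne=False)
    trunc, cutoff = truncate_recent(ped)
    excl = apply_exclusions(trunc, toy_configs(), cutoff)
    with pytest.warns(UserWarning, match="non-positive parental age"):
        table = assemble_offspring_table(ped, metrics, excl, toy_configs())
    assert "O" not in set(table.get("offspring_id", []))


# ---------------------------------------------------------------------------
# litter sampling
# ---------------------------------------------------------------------------

def _litter_table():
    rows = []
    for litter, size in (("a", 1), ("b", 2), ("c", 5)):
        for k in range(size):
            rows.append({"offspring_id": f"{litter}{k}", "litter_key": litter,
                         "species": "toy"})
    return pd.DataFrame(rows)


def test_sample_one_per_litter_sizes():
    out = sample_one_per_litter(_litter_table(), seed=0)
    assert len(out) == 3
    assert set(out["litter_key"]) == {"a", "b", "c"}
    assert "a0" in set(out["offspring_id"])  # singleton always kept


def test_sampling_determinism_and_seed_sensitivity():
    t = _litter_table()
    assert sample_one_per_litter(t, 5)["offspring_id"].tolist() == \
        sample_one_per_litter(t, 5)["offspring_id"].tolist()
    picks = {tuple(sample_one_per_litter(t, s)["offspring_id"])
             for s in range(12)}
    assert len(picks) > 1  # different seeds eventually differ


def test_sampling_invariant_to_row_order():
    t = _litter_table()
    shuffled = t.sample(frac=1.0, random_state=3).reset_index(drop=True)
    a = sorted(sample_one_per_litter(t, 9)["offspring_id"])
    b = sorted(sample_one_per_litter(shuffled, 9)["offspring_id"])
    assert a == b


def test_all_singletons_identity():
    t = _litter_table().drop_duplicates("litter_key")
    out = sample_one_per_litter(t, 1)
    assert sorted(out["offspring_id"]) == sorted(t["offspring_id"])


def test_make_replicates_contract():
    t = _litter_table()
    reps = make_replicates(t, n_replicates=5, base_seed=10)
    assert len(reps) == 5
    again = make_replicates(t, n_replicates=5, base_seed=10)
    for a, b in zip(reps, again):
        assert a["offspring_id"].tolist() == b["offspring_id"].tolist()
    full = set(t["offspring_id"])
    for rep in reps:
        assert set(rep["offspring_id"]) <= full
        assert len(rep) == 3


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def _predictor_table(values_by_species):
    rows = []
    for sp, vals in values_by_species.items():
        for i, v in enumerate(vals):
            row = {"offspring_id": f"{sp}{i}", "species": sp, "survival": 1,
                   "birth_program": "Europe", "birth_year": 2000,
                   "litter_key": f"{sp}{i}"}
            row.update({p: float(v) for p in PREDICTORS})
            rows.append(row)
    return pd.DataFrame(rows)


def test_standardize_center_scale():
    std = standardize_within_species(_predictor_table({"a": [1, 2, 3]}))
    assert std.data["dam_f"].tolist() == [-1.0, 0.0, 1.0]


def test_standardize_per_species_means():
    std = standardize_within_species(
        _predictor_table({"a": [1, 2, 3], "b": [10, 30, 50]}))
    for sp in ("a", "b"):
        grp = std.data[std.data.species == sp]
        for p in PREDICTORS:
            assert abs(grp[p].mean()) < 1e-10
            assert abs(grp[p].std(ddof=1) - 1.0) < 1e-10


def test_standardize_constant_column_warns():
    tab = _predictor_table({"a": [1, 2, 3]})
    tab["dam_f"] = 0.0
    with pytest.warns(UserWarning, match="constant within species"):
        std = standardize_within_species(tab)
    assert (std.data["dam_f"] == 0.0).all()


def test_standardize_back_transform_roundtrip():
    tab = _predictor_table({"a": [1, 5, 9], "b": [2, 4, 8, 16]})
    std = standardize_within_species(tab)
    for p in PREDICTORS:
        back = std.back_transform(p)
        assert np.allclose(back.to_numpy(),
                           std.data[p + "_raw"].to_numpy(), atol=1e-10)


@settings(max_examples=25, deadline=None)
@given(st.lists(st.floats(min_value=-1e4, max_value=1e4), min_size=3,
                max_size=30),
       st.integers(min_value=0, max_value=2 ** 16))
def test_standardize_roundtrip_property(vals, salt):
    tab = _predictor_table({"a": vals})
    std = standardize_within_species(tab)
    back = std.back_transform("offspring_f").to_numpy()
    assert np.allclose(back, np.asarray(vals, dtype=float),
                       atol=1e-8 * (1 + np.max(np.abs(vals))))


# ---------------------------------------------------------------------------
# G2+ subset
# ---------------------------------------------------------------------------

def test_subset_g2plus_rules():
    tab = _predictor_table({"a": [1, 2, 3, 4]})
    tab["dam_generation"] = [0.0, 1.0, 2.0, 1.0]
    tab["sire_generation"] = [1.0, 1.0, 0.5, 3.0]
    sub = subset_g2plus(tab)
    assert sorted(sub["offspring_id"]) == ["a1", "a3"]
    # after standardization the raw columns drive the subset
    std = standardize_within_species(tab)
    sub2 = subset_g2plus(std.data)
    assert sorted(sub2["offspring_id"]) == ["a1", "a3"]
    assert set(sub2.index) <= set(std.data.index)


# ---------------------------------------------------------------------------
# species config I/O
# ---------------------------------------------------------------------------

def test_load_species_configs(tmp_path):
    path = tmp_path / "species.yaml"
    path.write_text(
        "tortoise:\n  maturity_female_days: 2910\n"
        "  maturity_male_days: 2100\n  litter_rule: same_year\n"
        "devil:\n  maturity_female_days: 730\n  maturity_male_days: 730\n")
    cfgs = load_species_configs(path)
    assert cfgs["tortoise"].litter_rule == "same_year"
    assert cfgs["devil"].litter_rule == "same_day"
    assert cfgs["tortoise"].maturity_days("unknown") == 2100


def test_species_config_validation():
    with pytest.raises(ValueError):
        SpeciesConfig("x", -1, 100)
    with pytest.raises(ValueError):
        SpeciesConfig("x", 100, 100, litter_rule="same_week")
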