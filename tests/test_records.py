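"""Phenotype records: survival coding, design construction, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from threshlin.pedigree import Pedigree, inbreeding_coefficients
from threshlin.records import (CODE_ALIVE, CODE_DEAD, CODE_MISSING, KitRecord,
                               ModelSpec, RecordError, build_design,
                               code_survival, read_phenotypes,
                               records_to_frame, summarize_dataset)


def make_kit(i, litter="L1", dam="D1", litter_size=3, sb=2, sw=2, bw=50.0,
             **over):
    base = dict(kit_id=f"K{i}", dam_id=dam, litter_id=litter, parity="1",
                lactation="lactating", season="summer", nest="excellent",
                cannibalism="no", inside_nest="yes", sex="male",
                litter_size=litter_size, sb=sb, sw=sw, bw=bw)
    base.update(over)
    return KitRecord(**base)


def pedigree_for(records):
    ids = sorted({r.dam_id for r in records}) + [r.kit_id for r in records]
    dam_idx = {d: i for i, d in enumerate(sorted({r.dam_id for r in records}))}
    sire = np.full(len(ids), -1)
    dam = np.full(len(ids), -1)
    for j, r in enumerate(records):
        dam[len(dam_idx) + j] = dam_idx[r.dam_id]
    ped = Pedigree(ids, sire, dam)
    ped.f = inbreeding_coefficients(ped)
    return ped


class TestSurvivalCoding:
    @pytest.mark.parametrize("born,weaned,expected", [
        (False, None, (1, 0)),   # dead at birth -> weaning missing
        (True, False, (2, 1)),   # died while nursing
        (True, True, (2, 2)),    # weaned
        (True, None, (2, 0)),    # weaning outcome unknown
    ])
    def test_codes(self, born, weaned, expected):
        assert code_survival(born, weaned) == expected

    def test_dead_kit_cannot_have_weaning_outcome(self):
        with pytest.raises(RecordError):
            code_survival(False, True)

    def test_record_invariant_dead_at_birth(self):
        with pytest.raises(RecordError, match="dead at birth"):
            make_kit(1, sb=1, sw=2)

    def test_unknown_factor_level_rejected(self):
        with pytest.raises(RecordError, match="winter"):
            make_kit(1, season="winter")


class TestReading:
    def _write(self, tmp_path, rows, header=None):
        header = header or ("kit,dam,litter,parity,lactation,season,nest,"
                            "cannibalism,inside_nest,sex,litter_size,sb,sw,bw_g")
        path = tmp_path / "phen.csv"
        path.write_text(header + "\n" + "\n".join(rows) + "\n")
        return path

    def test_round_numbers_and_missing_bw(self, tmp_path):
        path = self._write(tmp_path, [
            "K1,D1,L1,1,lactating,summer,excellent,no,yes,male,2,2,2,48.5",
            "K2,D1,L1,1,lactating,summer,excellent,no,yes,female,2,1,0,",
        ])
        recs = read_phenotypes(path)
        assert len(recs) == 2
        assert recs[1].bw is None
        assert recs[1].sb == CODE_DEAD and recs[1].sw == CODE_MISSING

    def test_inconsistent_codes_rejected(self, tmp_path):
        path = self._write(tmp_path, [
            "K1,D1,L1,1,lactating,summer,excellent,no,yes,male,1,1,2,40",
        ])
        with pytest.raises(RecordError):
            read_phenotypes(path)

    def test_litter_size_cross_check(self, tmp_path):
        path = self._write(tmp_path, [
            "K1,D1,L1,1,lactating,summer,excellent,no,yes,male,5,2,2,48.5",
            "K2,D1,L1,1,lactating,summer,excellent,no,yes,male,5,2,2,51.0",
        ])
        with pytest.raises(RecordError, match="declared size 5"):
            read_phenotypes(path)


class TestDesign:
    def test_single_level_factors_give_intercept_only(self):
        recs = [make_kit(i) for i in range(6)]
        design = build_design(recs, pedigree_for(recs))
        assert design.x_names == ["intercept"]
        assert design.x.shape == (6, 1)

    def test_parity_contrasts_added(self):
        recs = [make_kit(i, parity=p) for i, p in enumerate("112233")]
        design = build_design(recs, pedigree_for(recs))
        assert "parity[2]" in design.x_names and "parity[3]" in design.x_names
        assert design.x.shape[1] == 3  # intercept + 2 contrasts

    def test_litter_size_covariate_is_centered(self):
        recs = ([make_kit(i, litter="L1", litter_size=2) for i in range(2)]
                + [make_kit(i + 2, litter="L2", litter_size=4,
                            dam="D2") for i in range(4)])
        design = build_design(recs, pedigree_for(recs),
                              ModelSpec(adjust_for_litter_size=True))
        col = design.x_names.index("litter_size")
        vals = design.x.toarray()[:, col]
        assert vals.sum() == pytest.approx(0.0)

    def test_study_shaped_grouping(self):
        # 208 litters over 81 does -> V has 208 columns, W has 81
        rng = np.random.default_rng(0)
        recs = []
        k = 0
        for lit in range(208):
            dam = f"D{lit % 81}"
            for _ in range(rng.integers(1, 4)):
                recs.append(make_kit(k, litter=f"L{lit}", dam=dam))
                k += 1
        design = build_design(recs, pedigree_for(recs))
        assert len(design.litter_ids) == 208
        assert len(design.doe_ids) == 81

    def test_kit_missing_from_pedigree(self):
        recs = [make_kit(0)]
        ped = Pedigree(["D1"], np.array([-1]), np.array([-1]))
        ped.f = inbreeding_coefficients(ped)
        with pytest.raises(RecordError, match="absent"):
            build_design(recs, ped)

    def test_litter_with_two_dams_rejected(self):
        recs = [make_kit(0, dam="D1"), make_kit(1, dam="D2")]
        with pytest.raises(RecordError, match="two dams"):
            build_design(recs, pedigree_for(recs))

    def test_mask_conservation(self):
        # unmasked weaning cells == kits alive at birth
        rng = np.random.default_rng(1)
        recs = []
        for i in range(40):
            sb = 2 if rng.random() < 0.9 else 1
            sw = 0 if sb == 1 else int(rng.choice([1, 2]))
            recs.append(make_kit(i, sb=sb, sw=sw))
        design = build_design(recs, pedigree_for(recs))
        observed_sw = np.sum(design.status[:, 1] != CODE_MISSING)
        assert observed_sw == sum(1 for r in recs if r.sb == CODE_ALIVE)


class TestSummaries:
    def test_toy_hand_arithmetic(self):
        recs = [make_kit(0, sb=1, sw=0, bw=40.0), make_kit(1, sb=1, sw=0, bw=50.0),
                make_kit(2, sb=2, sw=2, bw=60.0, litter="L2", dam="D2"),
                make_kit(3, sb=2, sw=2, bw=70.0, litter="L2", dam="D2")]
        for r in recs:
            r.litter_size = 2
        s = summarize_dataset(recs)
        assert s.bw_overall[1] == pytest.approx(55.0)
        assert s.bw_live[1] == pytest.approx(65.0)
        assert s.bw_dead[1] == pytest.approx(45.0)
        assert s.survival_birth_pct == pytest.approx(50.0)

    def test_all_alive(self):
        recs = [make_kit(i, sb=2, sw=2) for i in range(4)]
        s = summarize_dataset(recs)
        assert s.survival_birth_pct == 100.0
        assert s.bw_dead[0] == 0

    def test_factor_table_rows(self):
        recs = [make_kit(i) for i in range(3)]
        tab = summarize_dataset(recs).bw_by_factor
        assert set(tab["factor"]) == {"parity", "lactation", "season", "nest",
                                      "cannibalism", "inside_nest", "sex"}

    @given(st.lists(st.tuples(st.booleans(),
                              st.floats(10, 100, allow_nan=False)),
                    min_size=2, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_pooling_identity(self, kits):
        # overall mean == count-weighted mean of live and dead subgroup means
        recs = [make_kit(i, sb=2 if alive else 1, sw=2 if alive else 0, bw=bw)
                for i, (alive, bw) in enumerate(kits)]
        for r in recs:
            r.litter_size = len(recs)
        s = summarize_dataset(recs)
        n_live, mean_live, _ = s.bw_live
        n_dead, mean_dead, _ = s.bw_dead
        pooled = (n_live * (mean_live if n_live else 0.0)
                  + n_dead * (mean_dead if n_dead else 0.0)) / (n_live + n_dead)
        assert s.bw_overall[1] == pytest.approx(pooled, rel=1e-12)

    def test_round_trip_frame(self):
        recs = [make_kit(i) for i in range(3)]
        df = records_to_frame(recs)
        assert list(df["kit"]) == ["K0", "K1", "K2"]
        assert df.shape == (3, 14)
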