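"""Solo-LTR filters, ratios, insertion ages, and TE class summaries."""

import numpy as np
import pandas as pd
import pytest

from baokit import io, synthetic_data as sd
from baokit._util import mutate_dna, random_dna
from baokit.ltr_dynamics import (DEFAULT_LTR_RATE, SoloLtrReport, TEAnnotationSet,
                                 classify_solo_ltrs, ltr_insertion_age,
                                 solo_intact_ratio, te_summary)


def _gff_row(chrom, ftype, start, end, score, attrs):
    return {"chrom": chrom, "source": "t", "type": ftype, "start": start, "end": end,
            "score": score, "strand": "+", "phase": ".", "attributes": attrs}


def _intact(chrom, start, elem_id, ltr_len=300, internal_len=2000):
    rows = [_gff_row(chrom, "LTR_retrotransposon", start, start + 2 * ltr_len + internal_len - 1,
                     1000.0, {"ID": elem_id, "Classification": "LTR/Copia",
                              "Method": "structural", "Identity": "0.95"})]
    offs = [(0, ltr_len, "long_terminal_repeat"), (ltr_len, internal_len, "LTR_internal"),
            (ltr_len + internal_len, ltr_len, "long_terminal_repeat")]
    for i, (off, ln, t) in enumerate(offs):
        rows.append(_gff_row(chrom, t, start + off, start + off + ln - 1, 1000.0,
                             {"ID": f"{elem_id}_p{i}", "Parent": elem_id,
                              "Classification": "LTR/Copia", "Method": "structural",
                              "Identity": "0.95"}))
    return rows


def _candidate(chrom, start, length, name, identity=0.9, score=500.0):
    return _gff_row(chrom, "long_terminal_repeat", start, start + length - 1, score,
                    {"ID": name, "Name": name, "Classification": "LTR/Gypsy",
                     "Method": "homology", "Identity": f"{identity:.3f}"})


def _annotation(rows):
    return TEAnnotationSet.from_frame(pd.DataFrame(rows, columns=io.GFF_COLUMNS))


# ------------------------------------------------------------- classification

def test_planted_decoys_rejected_with_matching_rules():
    gff, truth = sd.sim_te_gff(25, 30, 6, seed=3)
    report = classify_solo_ltrs(TEAnnotationSet.from_frame(gff))
    expected = {c["id"]: ("solo" if c["label"] == "solo" else c["rule"])
                for c in truth["candidates"]}
    got = dict(zip(report.verdicts["te_id"], report.verdicts["verdict"]))
    assert got == expected


def test_all_solos_accepted_without_decoys():
    gff, truth = sd.sim_te_gff(10, 20, 0, seed=4)
    report = classify_solo_ltrs(TEAnnotationSet.from_frame(gff))
    assert (report.verdicts["verdict"] == "solo").all()


def test_short_candidate_fails_length_rule():
    rows = _intact("chr1", 1000, "E1") + [_candidate("chr1", 50_000, 90, "C1")]
    report = classify_solo_ltrs(_annotation(rows))
    assert report.verdicts.iloc[0]["verdict"] == "length"


def test_candidate_near_intact_fails_distance_rule():
    rows = _intact("chr1", 1000, "E1", ltr_len=300, internal_len=2000)
    # intact element ends at 1000+2600-1=3600; candidate 4 kb beyond it
    rows.append(_candidate("chr1", 3600 + 4000, 200, "C1"))
    report = classify_solo_ltrs(_annotation(rows))
    assert report.verdicts.iloc[0]["verdict"] == "distance"


def test_missing_identity_attribute_fails_identity_rule():
    cand = _candidate("chr1", 50_000, 200, "C1")
    del cand["attributes"]["Identity"]
    rows = _intact("chr1", 1000, "E1") + [cand]
    report = classify_solo_ltrs(_annotation(rows))
    assert report.verdicts.iloc[0]["verdict"] == "identity"


def test_no_intact_elements_skips_percentile_with_warning():
    rows = [_candidate("chr1", 50_000, 5000, "C1")]  # huge but no percentile basis
    report = classify_solo_ltrs(_annotation(rows))
    assert report.length_bound is None
    assert any("percentile" in w for w in report.warnings)
    assert report.verdicts.iloc[0]["verdict"] == "solo"


def test_verdict_pass_fail_is_filter_order_invariant():
    """Each rule is an independent predicate: a candidate passes iff it
    violates none, whatever the order; only the recorded label depends on
    order."""
    gff, truth = sd.sim_te_gff(15, 10, 6, seed=8)
    ann = TEAnnotationSet.from_frame(gff)
    report = classify_solo_ltrs(ann)
    bound = report.length_bound
    df = ann.records
    id_carriers = df[df["role"].isin(("intact", "ltr", "internal"))]
    targets = df[df["role"].isin(("candidate", "ltr", "internal"))]
    for cand in ann.by_role("candidate").itertuples():
        near = targets[(targets["chrom"] == cand.chrom) & (targets.index != cand.Index)]
        gap = np.maximum.reduce([
            near["start"].to_numpy() - cand.end - 1,
            cand.start - near["end"].to_numpy() - 1,
            np.zeros(len(near), dtype=int),
        ])
        up = id_carriers[(id_carriers["chrom"] == cand.chrom) & (id_carriers["end"] < cand.start)].nlargest(2, "end")
        down = id_carriers[(id_carriers["chrom"] == cand.chrom) & (id_carriers["start"] > cand.end)].nsmallest(2, "start")
        violations = [
            cand.length < 100,
            not (cand.identity >= 0.8),
            not (cand.score >= 300),
            bool(set(up["ltr_rt_id"]) & set(down["ltr_rt_id"])),
            bool(len(near)) and gap.min() < 5000,
            bound is not None and cand.length > bound,
        ]
        verdict = report.verdicts.set_index("te_id").loc[cand.te_id, "verdict"]
        assert (verdict == "solo") == (not any(violations))


# -------------------------------------------------------------------- ratios

def _report_with_counts(solo_by_chrom, intact_by_chrom):
    verdicts = pd.DataFrame(
        [(f"s{i}", c, 0, 0, "solo") for c, n in solo_by_chrom.items() for i in range(n)],
        columns=["te_id", "chrom", "start", "end", "verdict"],
    )
    return SoloLtrReport(
        verdicts=verdicts, length_bound=None,
        intact_counts=pd.Series(intact_by_chrom, dtype=int),
        solo_counts=pd.Series(solo_by_chrom, dtype=int),
    )


def test_ratio_arithmetic():
    rep = _report_with_counts({"chr1": 8}, {"chr1": 2})
    assert solo_intact_ratio(rep, "genome").iloc[0]["ratio"] == 4.0


def test_zero_solos_gives_zero_ratio():
    rep = _report_with_counts({}, {"chr1": 5})
    assert solo_intact_ratio(rep, "genome").iloc[0]["ratio"] == 0.0


def test_zero_intacts_flagged_undefined():
    rep = _report_with_counts({"chr1": 3}, {})
    row = solo_intact_ratio(rep, "chromosome").iloc[0]
    assert row["undefined"] and np.isnan(row["ratio"])


# ---------------------------------------------------------------------- ages

def test_identical_ltr_pair_has_zero_age():
    age = ltr_insertion_age("ACGT" * 100, "ACGT" * 100)
    assert age.age_years == 0.0


def test_one_percent_divergence_age_closed_form():
    rng = np.random.default_rng(0)
    a = random_dna(rng, 1000)
    b = list(a)
    for i in range(0, 1000, 100):  # exactly 10 substitutions -> p = 0.01
        b[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[i]]
    age = ltr_insertion_age(a, "".join(b))
    assert age.divergence_raw == pytest.approx(0.01)
    assert age.divergence_corrected == pytest.approx(0.010067, abs=1e-6)
    assert age.age_years == pytest.approx(0.010067 / (2 * 4.72e-9), rel=1e-4)


def test_raw_divergence_mode_matches_rate_arithmetic():
    rng = np.random.default_rng(1)
    a = random_dna(rng, 6250)
    b = list(a)
    for i in range(0, 59 * 100, 100):  # 59 substitutions / 6250 sites = 0.00944
        b[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[i]]
    age = ltr_insertion_age(a, "".join(b), jukes_cantor=False)
    assert age.divergence_raw == pytest.approx(0.00944)
    assert age.age_years == pytest.approx(1.0e6, rel=1e-9)


def test_saturated_divergence_is_an_error():
    with pytest.raises(ValueError, match="saturated"):
        ltr_insertion_age("A" * 200, "C" * 200)


def test_age_is_monotone_in_divergence():
    rng = np.random.default_rng(2)
    a = random_dna(rng, 2000)
    ages = []
    for n_subs in (0, 5, 20, 80, 200):
        b = list(a)
        for i in range(n_subs):
            pos = i * 9
            b[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[pos]]
        ages.append(ltr_insertion_age(a, "".join(b)).age_years)
    assert ages == sorted(ages)
    assert len(set(ages)) == len(ages)


# ------------------------------------------------------------------ summaries

def test_te_summary_percent_of_genome():
    rows = [_gff_row("chr1", "repeat_region", 1, 1000, 100.0,
                     {"ID": "T1", "Classification": "DNA/Mutator", "Method": "homology"})]
    out = te_summary(_annotation(rows), 10_000)
    assert out.iloc[0]["percent_of_genome"] == pytest.approx(10.0)


def test_te_summary_merges_overlapping_same_class_records():
    rows = [
        _gff_row("chr1", "repeat_region", 1, 100, 100.0,
                 {"ID": "T1", "Classification": "DNA/Mutator", "Method": "homology"}),
        _gff_row("chr1", "repeat_region", 50, 150, 100.0,
                 {"ID": "T2", "Classification": "DNA/Mutator", "Method": "homology"}),
    ]
    out = te_summary(_annotation(rows), 10_000)
    assert out.iloc[0]["bp_covered"] == 150


def test_te_summary_class_percentages_bounded():
    gff, _ = sd.sim_te_gff(10, 10, 0, seed=9, n_other_te=10)
    out = te_summary(TEAnnotationSet.from_frame(gff), 5_000_000)
    assert out.attrs["total_percent"] <= 100.0
    assert (out["percent_of_genome"] >= 0).all()


def test_te_summary_rejects_records_beyond_genome():
    rows = [_gff_row("chr1", "repeat_region", 1, 20_000, 100.0,
                     {"ID": "T1", "Classification": "DNA/Mutator", "Method": "homology"})]
    with pytest.raises(ValueError, match="T1"):
        te_summary(_annotation(rows), 10_000)
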