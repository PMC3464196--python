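import numpy as np
import pandas as pd
import pytest

from iescan import io, simulate, stats
from iescan.io import GeneAnnotation, IesRecord


# ---------------------------------------------------------------------------
# context


def _gene():
    return GeneAnnotation(
        gene_id="g1",
        scaffold="s1",
        start=100,
        end=400,
        strand="+",
        intervals=((100, 200, "exon"), (200, 230, "intron"), (230, 400, "exon")),
    )


@pytest.mark.parametrize(
    "p,expected",
    [
        (150, "exon"),
        (210, "intron"),
        (50, "intergenic"),
        (500, "intergenic"),
        (200, "intron"),  # half-open: exon end boundary joins the next interval
        (230, "exon"),
        (100, "exon"),
    ],
)
def test_classify_context(p, expected):
    rec = IesRecord("s1", p, "TAGG")
    ctx, gid = stats.classify_context(rec, [_gene()])
    assert ctx == expected
    assert (gid == "g1") is (expected != "intergenic")


# ---------------------------------------------------------------------------
# composition


def test_composition_gc_and_lengths():
    recs = [IesRecord("s", 0, "TATA"), IesRecord("s", 9, "TAGC")]
    out = stats.composition(recs)
    assert out["gc"] == pytest.approx(0.25)  # pooled: 2 GC / 8
    assert out["mean_length"] == 4 and out["n"] == 2
    assert stats.composition([recs[0]])["gc"] == 0.0
    assert stats.composition([recs[1]])["gc"] == 0.5


def test_composition_rejects_empty():
    with pytest.raises(ValueError):
        stats.composition([])


def test_generator_gc_parameter_is_recovered(small_dataset):
    recs = [t.as_ies_record() for t in small_dataset.truth]
    out = stats.composition(recs)
    assert out["gc"] == pytest.approx(0.20, abs=0.02)


# ---------------------------------------------------------------------------
# size periodicity


def _planted_lengths(spacing, n=20_000, seed=11):
    cfg = simulate.SimConfig(seed=3, peak_spacing=spacing)
    rng = np.random.default_rng(seed)
    return np.array([simulate._draw_length(cfg, rng) for _ in range(n)])


@pytest.mark.parametrize("spacing", [10.2, 12.0])
def test_periodicity_recovers_planted_spacing(spacing):
    hist = stats.SizeHistogram.from_lengths(_planted_lengths(spacing))
    fit = stats.size_periodicity(hist)
    assert fit.period == pytest.approx(spacing, abs=0.3)
    assert fit.n_peaks >= 3
    # the first peak holds the largest share and the second is depleted
    assert fit.first_peak_mass > 0.3
    assert fit.second_peak_ratio < 0.2


def test_periodicity_rejects_uniform_lengths():
    rng = np.random.default_rng(2)
    hist = stats.SizeHistogram.from_lengths(rng.integers(26, 151, 50_000))
    with pytest.raises(ValueError, match="insufficient periodic structure"):
        stats.size_periodicity(hist)


def test_size_histogram_totals():
    hist = stats.SizeHistogram.from_lengths([26, 26, 30, 200])
    assert hist.n == 3  # 200 is outside [26, 150]
    assert hist.counts[0] == 2 and hist.counts.sum() == hist.n


# ---------------------------------------------------------------------------
# end logo


def test_column_information_closed_forms():
    bg = {"A": 0.36, "T": 0.36, "G": 0.14, "C": 0.14}
    assert stats.column_information({"A": 0, "C": 0, "G": 0, "T": 1.0}, bg) == (
        pytest.approx(np.log2(1 / 0.36))
    )
    assert stats.column_information(
        {"A": 0.5, "C": 0, "G": 0, "T": 0.5}, bg
    ) == pytest.approx(np.log2(0.5 / 0.36))
    assert stats.column_information(bg, bg) == pytest.approx(0.0, abs=1e-12)


def test_end_logo_pools_both_ends():
    # element = seq + TA; both windows must start with the invariant T, A
    recs = [
        IesRecord("s", 0, "TACAGTCG" + "A" * 20),
        IesRecord("s", 9, "TATAGCAA" + "T" * 20),
    ]
    logo = stats.end_logo(recs, n_positions=8, gc=0.28)
    assert logo.n_sequences == 2
    np.testing.assert_allclose(logo.frequencies.sum(axis=1), 1.0)
    assert logo.frequencies.loc[1, "T"] == 1.0
    assert logo.frequencies.loc[2, "A"] == 1.0
    assert np.all(logo.information >= 0)
    assert logo.information[0] == pytest.approx(np.log2(1 / 0.36))


def test_end_logo_is_invariant_to_sequence_order():
    rng = np.random.default_rng(3)
    recs = [
        IesRecord("s", i, "TA" + "".join(rng.choice(list("ACGT"), size=30)))
        for i in range(20)
    ]
    a = stats.end_logo(recs)
    b = stats.end_logo(recs[::-1])
    np.testing.assert_allclose(a.information, b.information)


def test_end_logo_excludes_short_sequences():
    recs = [IesRecord("s", 0, "TA" + "G" * 30), IesRecord("s", 5, "TAGG")]
    logo = stats.end_logo(recs, n_positions=8)
    assert logo.n_sequences == 1 and logo.n_excluded == 1


# ---------------------------------------------------------------------------
# stop-codon classification


@pytest.mark.parametrize(
    "seq,phase,code,expected",
    [
        # phase 2: in-frame codons start at seq offsets 1, 4, 7, ...
        ("TACC" + "TGA" + "A" * 21, 2, "ciliate", "stop_containing"),
        ("TATAAGGGGGGGGGGGGGGGGGGGGGGGGGG", 1, "ciliate", "stopless"),
        ("TATAAGGGGGGGGGGGGGGGGGGGGGGGGGG", 1, "standard", "stop_containing"),
        ("TAG" * 9, 0, "ciliate", "stopless"),  # 27 bp, phase 0, no in-frame TGA
        ("TAG" * 9, 0, "standard", "stop_containing"),
    ],
)
def test_stop_classification_by_code(seq, phase, code, expected):
    assert (
        stats.classify_stop_in_frame(seq, phase, "GG", "GG", code=code) == expected
    )


def test_stop_classification_junction_codon_uses_flanks():
    # 28 bp IES at phase 0: the last in-frame codon is seq[-1] + two
    # downstream bases, T|GA -> TGA, a ciliate stop created at the junction
    seq = "TA" + "G" * 25 + "T"
    assert (
        stats.classify_stop_in_frame(seq, 0, flank_down="GA") == "stop_containing"
    )
    # without the downstream flank the junction codon is skipped
    assert stats.classify_stop_in_frame(seq, 0, flank_down="") == "stopless"
    # phase shifts the frame: same sequence at phase 1 has no in-frame stop
    assert (
        stats.classify_stop_in_frame(seq, 1, flank_up="G", flank_down="GA")
        == "stopless"
    )


# ---------------------------------------------------------------------------
# 3n bias chi-squared


def test_chi2_matches_two_cell_closed_form():
    res = stats.chi2_3n_bias((30, 70), (40, 60))
    # textbook oracle
    e3 = 100 * 0.4
    expected = (30 - e3) ** 2 / e3 + (70 - 60) ** 2 / 60
    assert res.chi2 == pytest.approx(expected)
    assert res.df == 1 and res.N == 100


def test_chi2_invariant_to_cell_label_swap():
    a = stats.chi2_3n_bias((7095, 16244), (3481, 6823))
    b = stats.chi2_3n_bias((16244, 7095), (6823, 3481))
    assert a.chi2 == pytest.approx(b.chi2)


def test_chi2_zero_when_proportions_match_null():
    res = stats.chi2_3n_bias((40, 60), (400, 600))
    assert res.chi2 == pytest.approx(0.0)
    assert res.p == pytest.approx(1.0)


def test_chi2_rejects_empty():
    with pytest.raises(ValueError):
        stats.chi2_3n_bias((0, 0), (10, 10))


# ---------------------------------------------------------------------------
# density vs expression


def _gene_table(densities, genes_per_bin=4):
    rows = []
    g = 0
    for i, d in enumerate(densities):
        for _ in range(genes_per_bin):
            rows.append(
                dict(
                    gene_id=f"g{g}",
                    cds_kb=1.0,
                    n_ies=d,
                    expression=float(g + 1),
                )
            )
            g += 1
    return pd.DataFrame(rows)


def test_density_equal_bins_have_zero_slope():
    table = _gene_table([2] * 5)
    _, slope, _ = stats.density_by_expression(table, n_bins=5)
    assert slope == pytest.approx(0.0, abs=1e-12)


def test_density_two_bin_hand_computed_slope():
    table = _gene_table([1.0, 0.5], genes_per_bin=3)
    binned, slope, intercept = stats.density_by_expression(table, n_bins=2)
    assert list(binned["density"]) == [1.0, 0.5]
    assert slope == pytest.approx(-0.5)


def test_density_inverse_expression_gives_negative_slope():
    rng = np.random.default_rng(4)
    expr = rng.uniform(1, 100, 300)
    table = pd.DataFrame(
        dict(
            gene_id=[f"g{i}" for i in range(300)],
            cds_kb=1.0,
            n_ies=rng.poisson(5.0 / expr * 10),
            expression=expr,
        )
    )
    _, slope, _ = stats.density_by_expression(table, n_bins=30)
    assert slope < 0


def test_density_requires_enough_distinct_values():
    table = _gene_table([1.0, 0.5])
    table["expression"] = 1.0
    with pytest.raises(ValueError, match="n_bins"):
        stats.density_by_expression(table, n_bins=2)


# ---------------------------------------------------------------------------
# positional uniformity


def test_uniform_grid_positions_accepted():
    res = stats.positional_uniformity(np.arange(50) * 20 + 10, 1000)
    assert res.verdict == "uniform"


def test_clustered_positions_rejected():
    rng = np.random.default_rng(9)
    res = stats.positional_uniformity(rng.uniform(0, 100, 100), 1000)
    assert res.verdict == "non_uniform" and res.p < 0.002
    assert res.statistic > 0.8  # all mass in the first 10%


def test_too_few_positions_is_inconclusive():
    res = stats.positional_uniformity([1, 2, 3], 1000)
    assert res.verdict == "inconclusive"
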