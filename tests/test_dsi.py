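"""Dyadic sociality index: filters, aggregation arithmetic, normalisation."""

import numpy as np
import pandas as pd
import pytest

import socbond as sb
from socbond import dsi
from socbond.tables import CohortTables


def _micro_tables(sample_rows, partner_rows, infants=None):
    samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "focal_id", "group_id", "date", "duration_min"]
    )
    samples["date"] = pd.to_datetime(samples["date"])
    partners = pd.DataFrame(
        partner_rows, columns=["sample_id", "partner_id", "behavior", "minutes"]
    )
    demography = pd.DataFrame(
        {
            "female_id": ["A", "B", "C"],
            "birth_date": pd.to_datetime(["1998-01-01"] * 3),
            "first_birth_date": pd.to_datetime(["2005-01-01"] * 3),
            "death_date": pd.to_datetime([pd.NaT] * 3),
            "censor_date": pd.to_datetime(["2014-10-01"] * 3),
        }
    )
    membership = pd.DataFrame(
        {"female_id": ["A", "B", "C"], "year": [0, 0, 0], "group_id": ["G"] * 3}
    )
    infants = (
        pd.DataFrame({"mother_id": [], "infant_birth_date": pd.to_datetime([])})
        if infants is None
        else infants
    )
    agonism = pd.DataFrame(
        {"date": pd.to_datetime([]), "group_id": [], "winner_id": [], "loser_id": []}
    )
    return CohortTables(samples, partners, demography, membership, infants, agonism)


def _subject_years(ids=("A", "B", "C")):
    return pd.DataFrame(
        {"female_id": list(ids), "year": 0, "group_id": "G", "included": True}
    )


def _spread_samples(focal, n, dur, start="2006-11-01"):
    days = pd.date_range(start, periods=n, freq="D")
    return [(f"{focal}{i}", focal, "G", d, dur) for i, d in enumerate(days)]


def test_dyad_year_hand_arithmetic():
    """600 focal minutes of A (grooming B for 30) plus 400 of B (grooming A
    for 20) give G_AB = 50/1000; resting components stay directional."""
    rows = _spread_samples("A", 20, 30.0) + _spread_samples("B", 20, 20.0)
    partner_rows = [
        ("A0", "B", "groom", 30.0),
        ("B0", "A", "groom", 20.0),
        ("A1", "B", "rest1m", 30.0),  # A's 60 resting minutes span two bouts
        ("A2", "B", "rest1m", 30.0),
        ("B1", "A", "rest1m", 10.0),
    ]
    t = _micro_tables(rows, partner_rows)
    d = dsi.compute_dyad_year(t, _subject_years(("A", "B")), sb.StudyConfig())
    rec = d[(d.id_i == "A") & (d.id_j == "B")].iloc[0]
    assert rec.T_dyad == pytest.approx(1000.0)
    assert rec.G_ij == pytest.approx(50.0 / 1000.0)
    assert rec.R_ij == pytest.approx(60.0 / 600.0)   # A's view
    assert rec.R_ji == pytest.approx(10.0 / 400.0)   # B's view, asymmetric
    assert rec.R_ij != rec.R_ji


def test_short_samples_are_discarded():
    rows = _spread_samples("A", 5, 19.0) + _spread_samples("B", 5, 20.0)
    t = _micro_tables(rows, [])
    filtered, _ = dsi.filter_records(t, sb.StudyConfig())
    assert set(filtered.focal_id) == {"B"}
    assert (filtered.duration_min >= 20).all()


def test_infant_exclusion_100_day_boundary():
    """A sample 99 days after the partner's infant birth is excluded for the
    dyad; the day-100 sample is retained."""
    birth = pd.Timestamp("2006-11-01")
    infants = pd.DataFrame({"mother_id": ["B"], "infant_birth_date": [birth]})
    rows = [
        ("A0", "A", "G", birth + pd.Timedelta(days=99), 30.0),
        ("A1", "A", "G", birth + pd.Timedelta(days=100), 30.0),
    ]
    t = _micro_tables(rows, [("A1", "B", "groom", 10.0)], infants=infants)
    d = dsi.compute_dyad_year(t, _subject_years(("A", "B")), sb.StudyConfig())
    rec = d[(d.id_i == "A") & (d.id_j == "B")].iloc[0]
    assert rec.T_dyad == pytest.approx(30.0)          # day-99 sample dropped
    assert rec.G_ij == pytest.approx(10.0 / 30.0)


def test_no_filters_bite_when_no_infants_and_full_bouts():
    rows = _spread_samples("A", 6, 30.0)
    t = _micro_tables(rows, [])
    filtered, windows = dsi.filter_records(t, sb.StudyConfig())
    assert len(filtered) == 6 and windows == {}


def test_median_dyad_scores_exactly_one():
    medians = pd.DataFrame({"year": [0], "G_med": [0.004], "R_med": [0.01]})
    rec = pd.DataFrame(
        {"group_id": ["G"], "year": [0], "id_i": ["A"], "id_j": ["B"],
         "T_dyad": [500.0], "G_ij": [0.004], "R_ij": [0.01], "R_ji": [0.01]}
    )
    out = dsi.compute_dsi(rec, medians)
    assert out.dsi.iloc[0] == pytest.approx(1.0, abs=1e-15)


@pytest.mark.parametrize(
    "g,rij,rji,expected",
    [(0.0, 0.0, 0.0, 0.0), (0.008, 0.0, 0.0, 1.0), (0.004, 0.02, 0.0, 1.0)],
)
def test_dsi_component_arithmetic(g, rij, rji, expected):
    medians = pd.DataFrame({"year": [0], "G_med": [0.004], "R_med": [0.01]})
    rec = pd.DataFrame(
        {"group_id": ["G"], "year": [0], "id_i": ["A"], "id_j": ["B"],
         "T_dyad": [500.0], "G_ij": [g], "R_ij": [rij], "R_ji": [rji]}
    )
    assert dsi.compute_dsi(rec, medians).dsi.iloc[0] == pytest.approx(expected)


def test_dsi_scales_linearly_in_each_component():
    medians = pd.DataFrame({"year": [0], "G_med": [0.004], "R_med": [0.01]})
    base = dict(group_id="G", year=0, id_i="A", id_j="B", T_dyad=500.0,
                G_ij=0.004, R_ij=0.01, R_ji=0.01)
    rec = pd.DataFrame([base, {**base, "G_ij": 0.008}, {**base, "R_ij": 0.02}])
    out = dsi.compute_dsi(rec, medians).dsi
    assert out.iloc[1] - out.iloc[0] == pytest.approx(0.5)
    assert out.iloc[2] - out.iloc[0] == pytest.approx(0.25)


def test_zero_median_year_raises():
    rec = pd.DataFrame(
        {"group_id": ["G"], "year": [0], "id_i": ["A"], "id_j": ["B"],
         "T_dyad": [500.0], "G_ij": [0.0], "R_ij": [0.0], "R_ji": [0.0]}
    )
    with pytest.raises(dsi.ZeroMedianError):
        dsi.compute_dsi(rec)


def test_year_medians_pool_directional_resting_components(small_study):
    dyads = small_study.dyads
    med = small_study.medians
    y = int(med.year.iloc[0])
    d = dyads[dyads.year == y]
    assert med[med.year == y].R_med.iloc[0] == pytest.approx(
        np.median(np.concatenate([d.R_ij, d.R_ji]))
    )
    assert med[med.year == y].G_med.iloc[0] == pytest.approx(np.median(d.G_ij))


class TestMatrixCorrelation:
    def test_proportional_matrices_correlate_perfectly(self):
        rng = np.random.default_rng(0)
        g = rng.random((6, 6))
        g = (g + g.T) / 2
        np.fill_diagonal(g, 0)
        r, p = dsi.matrix_correlation(g, 3.0 * g, n_permutations=200)
        assert r == pytest.approx(1.0)
        assert p < 0.05

    def test_single_perturbed_cell_keeps_high_correlation(self):
        rng = np.random.default_rng(1)
        g = rng.random((10, 10))
        g = (g + g.T) / 2
        np.fill_diagonal(g, 0)
        h = g.copy()
        h[0, 1] = h[1, 0] = h[0, 1] + 0.5
        r, _ = dsi.matrix_correlation(g, h, n_permutations=10)
        assert 0.9 < r < 1.0

    def test_small_roster_rejected(self):
        with pytest.raises(ValueError):
            dsi.matrix_correlation(np.zeros((2, 2)), np.zeros((2, 2)))

    def test_agrees_with_mantel_reference_implementation(self):
        """Cross-check r against scikit-bio's Mantel test on symmetric
        hollow matrices."""
        from skbio.stats.distance import DistanceMatrix, mantel

        rng = np.random.default_rng(2)
        g = rng.random((8, 8))
        g = (g + g.T) / 2
        np.fill_diagonal(g, 0)
        h = 0.6 * g + 0.4 * rng.random((8, 8))
        h = (h + h.T) / 2
        np.fill_diagonal(h, 0)
        r_mine, _ = dsi.matrix_correlation(g, h, n_permutations=10)
        r_ref, _, _ = mantel(DistanceMatrix(g), DistanceMatrix(h),
                             method="pearson", permutations=0)
        assert r_mine == pytest.approx(r_ref, abs=1e-12)
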