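"""Digestion, glycopeptide mass calculus, matching and site profiles."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fcgr3kit.glyco import (
    GlycanComposition,
    GlycopeptideMatch,
    PeptideSpec,
    classify_glycan,
    default_glycan_db,
    digest,
    find_sequons,
    glycopeptide_mass,
    match_precursors,
    peptide_mass,
    site_profile,
)
from fcgr3kit.synthetic import TOY_PROTEIN, pool_glycan_db


def brute_force_digest(seq: str, cut_after: set[str], max_missed: int):
    """Enumerate all substrings with valid cut-site boundaries."""
    sites = [
        i for i in range(1, len(seq))
        if seq[i - 1] in cut_after and seq[i] != "P"
    ]
    boundaries = [0] + sites + [len(seq)]
    out = set()
    for a, b in itertools.combinations(range(len(boundaries)), 2):
        internal = b - a - 1
        if internal <= max_missed:
            out.add((boundaries[a] + 1, boundaries[b]))
    return out


class TestDigest:
    def test_chymotrypsin_rule_application(self):
        peps = digest("GAKFSTR", enzymes={"chymotrypsin"}, max_missed=0,
                      min_length=1)
        assert {p.sequence for p in peps} == {"GAKF", "STR"}

    def test_gluc_never_cuts_before_proline(self):
        peps = digest("AEPG", enzymes={"gluc"}, max_missed=0, min_length=1)
        assert {p.sequence for p in peps} == {"AEPG"}

    def test_unknown_enzyme_rejected(self):
        with pytest.raises(ValueError, match="unknown enzyme"):
            digest("AAAA", enzymes={"trypsin"})

    @pytest.mark.parametrize("max_missed", [0, 1, 2])
    def test_matches_exhaustive_enumeration(self, max_missed):
        spans = {
            (p.start, p.end)
            for p in digest(TOY_PROTEIN, max_missed=max_missed, min_length=1)
        }
        assert spans == brute_force_digest(
            TOY_PROTEIN, set("FYWLME"), max_missed
        )

    def test_zero_missed_no_floor_reconstructs_sequence(self):
        peps = digest(TOY_PROTEIN, max_missed=0, min_length=1)
        ordered = sorted(peps, key=lambda p: p.start)
        assert "".join(p.sequence for p in ordered) == TOY_PROTEIN

    def test_length_floor_drops_short_peptides(self):
        peps = digest("GAKFSTR", enzymes={"chymotrypsin"}, max_missed=0,
                      min_length=4)
        assert {p.sequence for p in peps} == {"GAKF"}

    def test_missed_cleavage_counts_recorded(self):
        peps = digest("AFAFA", enzymes={"chymotrypsin"}, max_missed=2,
                      min_length=1)
        by_seq = {p.sequence: p.missed_cleavages for p in peps}
        assert by_seq["AFAFA"] == 2 or by_seq["AFAFA"] == 1
        assert by_seq["AF"] == 0


class TestMass:
    def test_bare_peptide_equals_composition_zero(self):
        pep = PeptideSpec("ACDEF", 1, 5)
        assert glycopeptide_mass(pep, GlycanComposition()) == pytest.approx(
            peptide_mass(pep)
        )

    def test_frozen_oligomannose_increment(self):
        pep = PeptideSpec("GNGSF", 1, 5)
        delta = glycopeptide_mass(
            pep, GlycanComposition(2, 5, 0, 0)
        ) - peptide_mass(pep)
        assert delta == pytest.approx(1216.42284, abs=1e-5)

    def test_carbamidomethyl_fixed_on_cysteine(self):
        plain = PeptideSpec("ACA", 1, 3, fixed_mods=())
        modded = PeptideSpec("ACA", 1, 3)
        assert peptide_mass(modded) - peptide_mass(plain) == pytest.approx(
            57.02146, abs=1e-5
        )

    def test_non_standard_residue_named_in_error(self):
        pep = PeptideSpec("AZA", 1, 3)
        with pytest.raises(ValueError, match="position 2"):
            peptide_mass(pep)

    @given(
        st.tuples(*[st.integers(0, 4)] * 4),
        st.tuples(*[st.integers(0, 4)] * 4),
    )
    @settings(max_examples=50, deadline=None)
    def test_mass_additivity(self, c1, c2):
        pep = PeptideSpec("GNGSF", 1, 5)
        comp1, comp2 = GlycanComposition(*c1), GlycanComposition(*c2)
        lhs = glycopeptide_mass(pep, comp1 + comp2) - glycopeptide_mass(
            pep, comp1
        )
        rhs = glycopeptide_mass(pep, comp2) - peptide_mass(pep)
        assert lhs == pytest.approx(rhs, abs=1e-9)


class TestClassification:
    @pytest.mark.parametrize(
        "comp,expected",
        [
            ((2, 5, 0, 0), "oligomannose"),
            ((2, 9, 0, 0), "oligomannose"),
            ((1, 0, 0, 0), "truncated"),
            ((2, 2, 0, 0), "truncated"),
            ((4, 5, 0, 1), "hybrid"),
            ((3, 5, 0, 0), "hybrid"),
            ((4, 4, 1, 2), "complex"),
            ((2, 5, 1, 0), "complex"),  # fucosylated: not oligomannose
            ((2, 3, 0, 0), "complex"),  # bare core
        ],
    )
    def test_rule_application(self, comp, expected):
        assert classify_glycan(GlycanComposition(*comp)) == expected

    @given(st.tuples(*[st.integers(0, 10)] * 4))
    @settings(max_examples=200, deadline=None)
    def test_total_function_over_compositions(self, counts):
        cls = classify_glycan(GlycanComposition(*counts))
        assert cls in ("oligomannose", "hybrid", "complex", "truncated")


class TestMatching:
    def test_exact_mass_gives_zero_ppm(self):
        pep = PeptideSpec("GNGSF", 44, 48)
        comp = GlycanComposition(2, 5, 0, 0)
        obs = pd.DataFrame(
            [{"mass": glycopeptide_mass(pep, comp), "spectral_count": 3,
              "log_probability": 2.0}]
        )
        matches = match_precursors(obs, [pep], [comp], TOY_PROTEIN)
        assert len(matches) == 1
        assert matches[0].ppm_error == pytest.approx(0.0, abs=1e-9)
        assert matches[0].site == 45

    def test_outside_tolerance_not_matched(self):
        pep = PeptideSpec("GNGSF", 44, 48)
        comp = GlycanComposition(2, 5, 0, 0)
        mass = glycopeptide_mass(pep, comp) * (1 + 25e-6)
        obs = pd.DataFrame(
            [{"mass": mass, "spectral_count": 3, "log_probability": 2.0}]
        )
        assert match_precursors(obs, [pep], [comp], TOY_PROTEIN, 10.0) == []

    def test_sequonless_peptides_never_match(self):
        pep = PeptideSpec("ADGKVRE", 1, 7)
        comp = GlycanComposition(2, 5, 0, 0)
        obs = pd.DataFrame(
            [{"mass": peptide_mass(pep) + comp.mass, "spectral_count": 3,
              "log_probability": 2.0}]
        )
        assert match_precursors(obs, [pep], [comp], TOY_PROTEIN) == []

    def test_planted_recovery_equals_brute_force(self, glyco_dataset):
        """Implementation == exhaustive cross-product oracle; full recovery."""
        table, truth = glyco_dataset
        peptides = digest(TOY_PROTEIN)
        db = pool_glycan_db()
        # pure precursor-mass semantics (ignore the site-assignment column)
        matches = match_precursors(
            table, peptides, db, TOY_PROTEIN, 10.0, site_column=None
        )

        brute = []
        theo = []
        for pep in peptides:
            sites = pep.sequons(TOY_PROTEIN)
            for comp in db:
                for site in sites:
                    theo.append((pep, site, comp, glycopeptide_mass(pep, comp)))
        for row in table.itertuples(index=False):
            for pep, site, comp, m in theo:
                if abs(row.mass - m) / m * 1e6 <= 10.0:
                    brute.append((pep.start, pep.end, site, comp.key(),
                                  round(row.mass, 6)))
        got = {
            (m.peptide.start, m.peptide.end, m.site, m.composition.key(),
             round(m.observed_mass, 6))
            for m in matches
        }
        assert got == set(brute)
        # every planted row is recovered at its own site
        assert {m.site for m in matches} >= set(truth["sites"])
        matched_masses = {round(m.observed_mass, 6) for m in matches}
        assert matched_masses == {round(m, 6) for m in table["mass"]}


class TestSiteProfile:
    def _match(self, site, comp, count, logp):
        pep = PeptideSpec("GNGSF", 44, 48)
        return GlycopeptideMatch(
            peptide=pep, site=site, composition=comp,
            theoretical_mass=1000.0, observed_mass=1000.0, ppm_error=0.0,
            spectral_count=count, log_probability=logp,
        )

    def test_single_spectrum_match_excluded(self):
        m = self._match(45, GlycanComposition(4, 4, 1, 0), 1, 2.0)
        prof = site_profile([m], 45)
        assert prof.total_spectra == 0
        assert prof.top_n == []
        assert prof.filter_audit["excluded_low_spectra"] == 1

    def test_low_log_probability_excluded(self):
        m = self._match(45, GlycanComposition(4, 4, 1, 0), 5, 0.5)
        prof = site_profile([m], 45)
        assert prof.total_spectra == 0
        assert prof.filter_audit["excluded_low_log_prob"] == 1

    def test_fractions_sum_to_one(self, glyco_dataset):
        table, truth = glyco_dataset
        matches = match_precursors(
            table, digest(TOY_PROTEIN), pool_glycan_db(), TOY_PROTEIN
        )
        for site in truth["sites"]:
            prof = site_profile(matches, site)
            assert sum(prof.class_fractions.values()) == pytest.approx(1.0)

    def test_fraction_invariance_under_count_scaling(self):
        comps = [
            (GlycanComposition(4, 4, 1, 0), 30),
            (GlycanComposition(2, 5, 0, 0), 10),
            (GlycanComposition(3, 5, 0, 0), 60),
        ]
        base = site_profile(
            [self._match(45, c, n, 2.0) for c, n in comps], 45
        )
        scaled = site_profile(
            [self._match(45, c, 7 * n, 2.0) for c, n in comps], 45
        )
        assert base.class_fractions == scaled.class_fractions

    def test_topn_ranked_with_deterministic_ties(self):
        comps = [
            (GlycanComposition(4, 4, 1, 0), 10),
            (GlycanComposition(2, 5, 0, 0), 10),
            (GlycanComposition(3, 5, 0, 0), 25),
        ]
        prof = site_profile(
            [self._match(45, c, n, 2.0) for c, n in comps], 45, top_n=10
        )
        assert [c.key() for c, _ in prof.top_n] == [
            (3, 5, 0, 0), (2, 5, 0, 0), (4, 4, 1, 0)
        ]

    def test_planted_fraction_recovery(self, clean_glyco_dataset):
        """Class fractions at each site recover the plant (multinomial noise)."""
        table, truth = clean_glyco_dataset
        matches = match_precursors(
            table, digest(TOY_PROTEIN), pool_glycan_db(), TOY_PROTEIN
        )
        for site in truth["sites"]:
            prof = site_profile(matches, site)
            planted = truth["planted_mixture"][str(site)]
            for cls, frac in planted.items():
                assert prof.class_fractions[cls] == pytest.approx(
                    frac, abs=0.03
                )
            realized = truth["post_filter_class_fractions"][str(site)]
            for cls, frac in realized.items():
                assert prof.class_fractions[cls] == pytest.approx(
                    frac, abs=1e-9
                )

    def test_default_db_covers_every_pool_composition(self):
        db = set(c.key() for c in default_glycan_db())
        for comp in pool_glycan_db():
            assert comp.key() in db


def test_sequon_detection_rules():
    assert find_sequons("ANGSA") == [2]
    assert find_sequons("ANPSA") == []   # X may not be proline
    assert find_sequons("ANGAA") == []   # needs S/T at +2
    assert find_sequons(TOY_PROTEIN) == [45, 64, 162]
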