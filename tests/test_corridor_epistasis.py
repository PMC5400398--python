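"""Neutral corridor construction, verdicts, mutation effects, sign epistasis."""

import math
from collections import Counter

import numpy as np
import pytest

from hbcorridor import (
    Corridor, PhenotypeRecord, build_corridor, build_space, ci95_of_mean,
    classify_genotype, classify_interval, classify_pathways, decode_label,
    detect_sign_epistasis, enumerate_pathways, mutation_effects,
    pathways_through,
)
from hbcorridor.corridor_epistasis import (
    ACCESSIBLE, INACCESSIBLE, MARGINAL, MARGINALLY_BELOW, STRICTLY_BELOW, WITHIN,
)

from conftest import make_toy_panel


def _rec(label, mean, ci, treatment="KCl_IHP", se=None):
    if se is None:
        se = (ci[1] - ci[0]) / 8.0 or 0.1
    return PhenotypeRecord(genotype_label=label, treatment=treatment,
                           p50_mean=mean, p50_se=se, n50_mean=2.0, n50_se=0.1,
                           n_replicates=3, ci95=ci)


def test_corridor_from_endpoint_limits():
    cor = build_corridor(_rec("ANC", 30.0, (28.0, 32.0)),
                         _rec("DESC", 36.0, (33.0, 39.0)))
    assert (cor.floor, cor.ceiling) == (28.0, 39.0)
    assert cor.direction == "increasing"


def test_degenerate_corridor_flagged():
    r = _rec("ANC", 30.0, (28.0, 32.0))
    cor = build_corridor(r, _rec("ANC", 30.0, (28.0, 32.0)))
    assert cor.direction == "degenerate"
    assert (cor.floor, cor.ceiling) == (28.0, 32.0)


def test_corridor_requires_matching_treatment():
    with pytest.raises(ValueError, match="treatment"):
        build_corridor(_rec("A", 30.0, (28.0, 32.0), treatment="stripped"),
                       _rec("B", 36.0, (33.0, 39.0), treatment="KCl_IHP"))


def test_fixture_floor_is_ancestor_lower_limit(kcl_ihp_records):
    cor = build_corridor(kcl_ihp_records["GVAI"], kcl_ihp_records["SIVV"])
    assert cor.floor == kcl_ihp_records["GVAI"].ci95[0]
    assert cor.ceiling == kcl_ihp_records["SIVV"].ci95[1]


@pytest.mark.parametrize("mean,ci,expected", [
    (12.0, (10.0, 14.0), STRICTLY_BELOW),   # CI entirely below the floor
    (27.0, (25.0, 29.0), MARGINALLY_BELOW),  # mean below, CI straddles floor
    (33.0, (31.0, 35.0), WITHIN),
])
def test_genotype_classification_rules(mean, ci, expected):
    cor = Corridor(trait="P50", treatment="KCl_IHP", floor=28.0, ceiling=39.0,
                   ancestor_label="A", descendant_label="D", direction="increasing")
    verdict = classify_genotype(_rec("X", mean, ci), cor)
    assert verdict.status == expected


def test_epsilon_marginal_rule():
    cor = Corridor(trait="P50", treatment="KCl_IHP", floor=28.0, ceiling=38.0,
                   ancestor_label="A", descendant_label="D", direction="increasing")
    # CI clears the floor by 0.3 < 0.05 * width (0.5): marginal under epsilon rule
    assert classify_interval(27.0, (26.5, 27.7), cor)[0] == STRICTLY_BELOW
    assert classify_interval(27.0, (26.5, 27.7), cor,
                             marginal_rule="epsilon")[0] == MARGINALLY_BELOW


def test_negation_equivariance():
    """Negating the trait swaps below<->above and preserves counts."""
    cor = Corridor(trait="P50", treatment="KCl_IHP", floor=28.0, ceiling=39.0,
                   ancestor_label="A", descendant_label="D", direction="increasing")
    neg = Corridor(trait="P50", treatment="KCl_IHP", floor=-39.0, ceiling=-28.0,
                   ancestor_label="A", descendant_label="D", direction="decreasing")
    rng = np.random.default_rng(11)
    for _ in range(200):
        mean = float(rng.uniform(5, 60))
        half = float(rng.uniform(0.5, 6))
        status, _ = classify_interval(mean, (mean - half, mean + half), cor)
        flipped, _ = classify_interval(-mean, (-mean - half, -mean + half), neg)
        assert flipped == status.replace("below", "x").replace("above", "below") \
            .replace("x", "above")


def test_fixture_pathway_counts(panel, kcl_ihp_records):
    cor = build_corridor(kcl_ihp_records["GVAI"], kcl_ihp_records["SIVV"])
    verdicts, counts = classify_pathways(enumerate_pathways(panel),
                                         kcl_ihp_records, cor)
    assert counts[INACCESSIBLE] == 12
    assert counts[MARGINAL] == 4
    assert counts[ACCESSIBLE] == 8
    assert sum(counts.values()) == 24
    # every marginal pathway is limited by the planted marginal genotype
    for v in verdicts:
        if v.status == MARGINAL:
            assert v.limiting_genotypes == ("GIAV",)


def test_flat_landscape_fully_accessible(panel):
    records = {
        g.label: _rec(g.label, 30.0, (29.0, 31.0))
        for g in build_space(panel).genotypes
    }
    cor = build_corridor(records["GVAI"], records["SIVV"])
    _, counts = classify_pathways(enumerate_pathways(panel), records, cor)
    assert counts == Counter({ACCESSIBLE: 24, MARGINAL: 0, INACCESSIBLE: 0})


def test_missing_record_names_genotype(panel, kcl_ihp_records):
    records = dict(kcl_ihp_records)
    del records["GIVI"]
    cor = build_corridor(records["GVAI"], records["SIVV"])
    with pytest.raises(KeyError, match="GIVI"):
        classify_pathways(enumerate_pathways(panel), records, cor)


def test_strict_pathway_count_matches_enumeration(panel, kcl_ihp_records):
    """Two routes to the same number: corridor verdicts vs direct enumeration."""
    cor = build_corridor(kcl_ihp_records["GVAI"], kcl_ihp_records["SIVV"])
    _, counts = classify_pathways(enumerate_pathways(panel), kcl_ihp_records, cor)
    strict = [lbl for lbl, r in kcl_ihp_records.items()
              if classify_genotype(r, cor).status == STRICTLY_BELOW]
    count, _ = pathways_through(panel, strict)
    assert counts[INACCESSIBLE] == count


# ---------------------------------------------------------- mutation effects

def _additive_records(panel, site_effects, noise=None, se=0.0):
    """ln P50 = 3 + sum of per-site effects (+ optional planted residuals)."""
    records = {}
    for g in build_space(panel).genotypes:
        ln_p50 = 3.0 + sum(e for e, s in zip(site_effects, g.states) if s)
        if noise is not None:
            ln_p50 += noise[g.label]
        p50 = math.exp(ln_p50)
        records[g.label] = PhenotypeRecord(
            genotype_label=g.label, treatment="KCl_IHP", p50_mean=p50,
            p50_se=se * p50, n50_mean=2.0, n50_se=0.1, n_replicates=3,
            ci95=ci95_of_mean(p50, se * p50, 3),
        )
    return records


def test_additive_landscape_has_uniform_effects():
    toy = make_toy_panel(3)
    effects = mutation_effects(_additive_records(toy, [0.2, -0.1, 0.05]), toy)
    assert len(effects) == 3 * 2 ** 2
    for idx, expected in zip((1, 2, 3), (0.2, -0.1, 0.05)):
        deltas = [e.delta for e in effects if e.site_index == idx]
        assert np.allclose(deltas, expected)


def test_effects_match_direct_recomputation(panel, kcl_ihp_records):
    effects = mutation_effects(kcl_ihp_records, panel, treatment="KCl_IHP")
    assert len(effects) == 4 * 2 ** 3
    for e in effects:
        b = kcl_ihp_records[e.background_label]
        m = kcl_ihp_records[e.mutant_label]
        assert e.delta == pytest.approx(math.log(m.p50_mean) - math.log(b.p50_mean))
        # background and mutant differ exactly at the named site
        gb = decode_label(e.background_label, panel)
        gm = decode_label(e.mutant_label, panel)
        assert gb.hamming(gm) == 1
        assert not gb.states[e.site_index - 1] and gm.states[e.site_index - 1]


def test_incomplete_landscape_rejected(panel, kcl_ihp_records):
    records = dict(kcl_ihp_records)
    del records["SVVI"]
    with pytest.raises(KeyError, match="SVVI"):
        mutation_effects(records, panel)


def test_fixture_sign_epistasis_at_beta112(panel, kcl_ihp_records):
    """The β112 substitution lowers P50 on SVAI but rescues it on SIAI."""
    effects = mutation_effects(kcl_ihp_records, panel, treatment="KCl_IHP")
    reports = {r.site_index: r for r in detect_sign_epistasis(effects)}
    site4 = reports[4]
    assert site4.flagged
    assert "SVAI" in site4.negative_backgrounds
    assert "SIAI" in site4.positive_backgrounds
    assert any(w == ("SVAI", "SIAI") for w in site4.witnesses)


def test_single_site_panel_never_flagged():
    toy = make_toy_panel(1)
    effects = mutation_effects(_additive_records(toy, [0.5]), toy)
    reports = detect_sign_epistasis(effects)
    assert len(reports) == 1 and not reports[0].flagged


def test_no_false_flags_on_random_additive_landscapes():
    """1000 noise-free additive landscapes: sign epistasis is never called."""
    toy = make_toy_panel(3)
    rng = np.random.default_rng(99)
    for _ in range(1000):
        site_effects = rng.uniform(-0.5, 0.5, size=3)
        effects = mutation_effects(_additive_records(toy, site_effects), toy)
        assert not any(r.flagged for r in detect_sign_epistasis(effects))
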