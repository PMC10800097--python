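"""Shared fixtures and hand-derived oracle expectations.

``CENSUS_EXPECTED`` freezes, for every per-combination census row, the
heterodimer set and unpaired remainder worked out by hand against the
canonical 24-pair repertoire (beta1: alpha1-11+alphaV; beta2: aL/aM/aX/aD;
beta3: a2b/aV; beta4: a6; beta5/6/8: aV; beta7: a4/aE).  The row
("ITGB1","ITGB3","ITGA2B","ITGAV","ITGAM") is the one combination where a
naive reading of the source census disagrees with the repertoire: with
ITGB1 and ITGB3 present, ITGAV necessarily forms aVb1 and aVb3, so the
cell carries three potential heterodimers.
"""

import pytest

from ctcintegrins import build_fixture, build_pairing_table, generate_cohort
from ctcintegrins.synthetic_cohort import CohortParams, FixtureSpec

# (expressed genes, expected group, expected dimers, expected unpaired)
CENSUS_EXPECTED = [
    (("ITGB1", "ITGA2"), 3, {("ITGA2", "ITGB1")}, set()),
    (("ITGB1", "ITGA4", "ITGAE"), 3, {("ITGA4", "ITGB1")}, {"ITGAE"}),
    (("ITGB1", "ITGA6"), 3, {("ITGA6", "ITGB1")}, set()),
    (("ITGB1", "ITGAV"), 3, {("ITGAV", "ITGB1")}, set()),
    (("ITGB2", "ITGAM"), 4, {("ITGAM", "ITGB2")}, set()),
    (("ITGB2", "ITGAM", "ITGAL"), 4,
     {("ITGAM", "ITGB2"), ("ITGAL", "ITGB2")}, set()),
    (("ITGB3", "ITGA2B"), 5, {("ITGA2B", "ITGB3")}, set()),
    (("ITGB3", "ITGA2B", "ITGA5"), 5, {("ITGA2B", "ITGB3")}, {"ITGA5"}),
    (("ITGB3", "ITGA2B", "ITGAE"), 5, {("ITGA2B", "ITGB3")}, {"ITGAE"}),
    (("ITGB1", "ITGB2", "ITGAE", "ITGA2B", "ITGA4"), 6,
     {("ITGA4", "ITGB1")}, {"ITGB2", "ITGAE", "ITGA2B"}),
    (("ITGB1", "ITGB2", "ITGAE", "ITGAL"), 6,
     {("ITGAL", "ITGB2")}, {"ITGB1", "ITGAE"}),
    (("ITGB1", "ITGB2", "ITGB3", "ITGAE", "ITGAL"), 6,
     {("ITGAL", "ITGB2")}, {"ITGB1", "ITGB3", "ITGAE"}),
    (("ITGB1", "ITGB3", "ITGB5", "ITGA2B"), 6,
     {("ITGA2B", "ITGB3")}, {"ITGB1", "ITGB5"}),
    (("ITGB1", "ITGB3", "ITGB5", "ITGA2B", "ITGA6"), 6,
     {("ITGA2B", "ITGB3"), ("ITGA6", "ITGB1")}, {"ITGB5"}),
    (("ITGB1", "ITGB3", "ITGB5", "ITGA2B", "ITGA2"), 6,
     {("ITGA2B", "ITGB3"), ("ITGA2", "ITGB1")}, {"ITGB5"}),
    (("ITGB1", "ITGB3", "ITGB5", "ITGA2B", "ITGAE"), 6,
     {("ITGA2B", "ITGB3")}, {"ITGB1", "ITGB5", "ITGAE"}),
    (("ITGB1", "ITGB3", "ITGB5", "ITGA2B", "ITGAM"), 6,
     {("ITGA2B", "ITGB3")}, {"ITGB1", "ITGB5", "ITGAM"}),
    (("ITGB1", "ITGB3", "ITGB5", "ITGA2B", "ITGA2", "ITGA6", "ITGAE",
      "ITGAM"), 6,
     {("ITGA2B", "ITGB3"), ("ITGA2", "ITGB1"), ("ITGA6", "ITGB1")},
     {"ITGB5", "ITGAE", "ITGAM"}),
    (("ITGB1", "ITGB3", "ITGB5", "ITGA2", "ITGA5"), 6,
     {("ITGA2", "ITGB1"), ("ITGA5", "ITGB1")}, {"ITGB3", "ITGB5"}),
    (("ITGB1", "ITGB3", "ITGA2B"), 6, {("ITGA2B", "ITGB3")}, {"ITGB1"}),
    (("ITGB1", "ITGB3", "ITGA2B", "ITGA6"), 6,
     {("ITGA2B", "ITGB3"), ("ITGA6", "ITGB1")}, set()),
    (("ITGB1", "ITGB3", "ITGA2B", "ITGAV", "ITGAM"), 6,
     {("ITGA2B", "ITGB3"), ("ITGAV", "ITGB1"), ("ITGAV", "ITGB3")},
     {"ITGAM"}),
    (("ITGB1", "ITGB3", "ITGA6"), 6, {("ITGA6", "ITGB1")}, {"ITGB3"}),
    (("ITGB3", "ITGB5", "ITGA2B"), 6, {("ITGA2B", "ITGB3")}, {"ITGB5"}),
    (("ITGB4",), 7, set(), {"ITGB4"}),
    (("ITGB4", "ITGB2"), 7, set(), {"ITGB4", "ITGB2"}),
    (("ITGB4", "ITGB1", "ITGA4", "ITGAE"), 7,
     {("ITGA4", "ITGB1")}, {"ITGB4", "ITGAE"}),
    (("ITGB4", "ITGB1", "ITGA6", "ITGAE", "ITGAV"), 8,
     {("ITGA6", "ITGB4"), ("ITGA6", "ITGB1"), ("ITGAV", "ITGB1")},
     {"ITGAE"}),
    (("ITGB4", "ITGB1", "ITGB3", "ITGB5", "ITGA2", "ITGA5", "ITGA6",
      "ITGAV"), 8,
     {("ITGA6", "ITGB4"), ("ITGA6", "ITGB1"), ("ITGAV", "ITGB1"),
      ("ITGA2", "ITGB1"), ("ITGA5", "ITGB1"), ("ITGAV", "ITGB3"),
      ("ITGAV", "ITGB5")}, set()),
    (("ITGB4", "ITGB1", "ITGA2", "ITGA5", "ITGA6", "ITGAV"), 8,
     {("ITGA6", "ITGB4"), ("ITGA6", "ITGB1"), ("ITGAV", "ITGB1"),
      ("ITGA2", "ITGB1"), ("ITGA5", "ITGB1")}, set()),
    (("ITGB4", "ITGB1", "ITGA2", "ITGA5", "ITGA6", "ITGAE", "ITGAV"), 8,
     {("ITGA6", "ITGB4"), ("ITGA6", "ITGB1"), ("ITGAV", "ITGB1"),
      ("ITGA2", "ITGB1"), ("ITGA5", "ITGB1")}, {"ITGAE"}),
]


@pytest.fixture(scope="session")
def pairing_table():
    return build_pairing_table()


@pytest.fixture(scope="session")
def census_fixture():
    """Deterministic 445-CTC census fixture plus 1,000 background cells."""
    return build_fixture(FixtureSpec(), seed=0)


@pytest.fixture(scope="session")
def planted_cohort():
    """Stochastic cohort: 500 cells/group, 26 elevated panel genes and 14
    planted DE genes in the alpha6-beta4 group, seed 0."""
    return generate_cohort(CohortParams(), seed=0)
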