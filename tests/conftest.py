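import pytest

from betalift import (ArmCounts, BetaParams, TwoByTwoTable, fixed_paper_cohort,
                      write_cohort_csv)

# Reference 2x2 table: exposed arm (13 successes, 11 failures),
# reference arm (48, 71); priors Beta(4,6) / Beta(3,7).
PAPER_TABLE = TwoByTwoTable(13, 11, 48, 71)
PAPER_EXPOSED = ArmCounts(13, 11)
PAPER_REFERENCE = ArmCounts(48, 71)
PRIOR_EXPOSED = BetaParams(4, 6)
PRIOR_REFERENCE = BetaParams(3, 7)
POSTERIOR_EXPOSED = BetaParams(17, 17)
POSTERIOR_REFERENCE = BetaParams(51, 78)


@pytest.fixture(scope="session")
def paper_cohort():
    return fixed_paper_cohort()


@pytest.fixture()
def paper_cohort_csv(tmp_path, paper_cohort):
    """The fixture cohort written to disk, with the schema to re-read it."""
    path = tmp_path / "cohort.csv"
    schema = write_cohort_csv(paper_cohort, path)
    return path, schema
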