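import numpy as np
import pytest

from ddmpriors.corpus import (Corpus, ParameterEstimate, ParameterKind,
                              RTUnit, ReportingLevel, Software)


def make_estimate(**kw):
    """A valid estimate with overridable fields, for terse test setup."""
    base = dict(
        article_id="A01", study_id="A01_s1", condition_id="c01",
        participant_id=None, kind=ParameterKind.V, value=2.0,
        s_reported=1.0, software=Software.OTHER, rt_unit=RTUnit.UNKNOWN,
        reporting_level=ReportingLevel.AGGREGATED, constraint_group="g1",
        n_participants=20, task="lexical decision",
        population="non-clinical")
    base.update(kw)
    return ParameterEstimate(**base)


@pytest.fixture
def tiny_corpus():
    """One article, one condition: a full (v, a, zr, ter) set in seconds."""
    rows = [
        make_estimate(kind=ParameterKind.V, value=2.0, constraint_group="gv"),
        make_estimate(kind=ParameterKind.A, value=1.2, constraint_group="ga"),
        make_estimate(kind=ParameterKind.Z_R, value=0.45,
                      constraint_group="gz"),
        make_estimate(kind=ParameterKind.T_ER, value=0.35,
                      constraint_group="gt"),
    ]
    return Corpus(estimates=tuple(rows))


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
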