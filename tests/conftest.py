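import datetime as dt

import pytest

from fnepisodes.datamodel import (ClaimsDataset, EnrollmentSpan, MedicalClaim,
                                  Member, PharmacyClaim, load_codesets,
                                  load_cpi_table)

D = dt.date
_counter = {"n": 0}


def med(member, day, setting="other_outpatient", dx=(), proc=(), paid=0.0, discharge=None):
    _counter["n"] += 1
    return MedicalClaim(f"c{_counter['n']:05d}", member, day, discharge, setting,
                        tuple(dx), tuple(proc), paid)


def rx(member, day, drug, paid=0.0):
    _counter["n"] += 1
    return PharmacyClaim(f"r{_counter['n']:05d}", member, day, drug, paid)


def member(member_id, birth_year=1960, sex="female", payer="commercial", region="south"):
    return Member(member_id, birth_year, sex, payer, region)


def dataset(medical=(), pharmacy=(), enrollment=(), members=()):
    mems = {m.member_id: m for m in members}
    ids = ({c.member_id for c in medical} | {c.member_id for c in pharmacy}
           | {s.member_id for s in enrollment})
    for mid in sorted(ids - set(mems)):
        mems[mid] = member(mid)
    if not enrollment:
        # blanket enrollment so eligibility never interferes unless a test
        # constructs spans explicitly
        enrollment = [EnrollmentSpan(mid, D(2013, 1, 1), D(2023, 1, 1)) for mid in sorted(mems)]
    return ClaimsDataset(members=mems, enrollment=list(enrollment),
                         medical=list(medical), pharmacy=list(pharmacy))


@pytest.fixture(scope="session")
def codesets():
    return load_codesets()


@pytest.fixture(scope="session")
def cpi():
    return load_cpi_table()


def fn_index_claims(member_id, day, *, inpatient=True, discharge=None):
    """Claims that make ``day`` a candidate index date for ``member_id``."""
    if inpatient:
        return [med(member_id, day, "inpatient", dx=["D70.9", "R50.9"],
                    discharge=discharge or day + dt.timedelta(days=3))], []
    return ([med(member_id, day, "emergency_room", dx=["D70.9", "R50.9"])],
            [rx(member_id, day, "LVX500")])


def qualifying_member_claims(member_id, index, *, chemo_offset=10, inpatient=True):
    """A minimal fully-qualifying episode: chemo in window + index event."""
    m, p = fn_index_claims(member_id, index, inpatient=inpatient)
    m.append(med(member_id, index - dt.timedelta(days=chemo_offset),
                 proc=["J9201"]))
    return m, p
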