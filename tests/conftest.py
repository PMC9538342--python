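import pytest

from g6pd_screen.cohort import (
    CohortTable,
    InfantRecord,
    Sex,
    VariantCall,
    Zygosity,
    reference_cohort,
)


def make_record(
    rid: str,
    sex: str = "male",
    ratio: float = 0.3,
    panel_variant: str | None = "c.1388G>A",
    sanger: str | None = None,
    sanger_negative: bool = False,
    zygosity: str | None = None,
) -> InfantRecord:
    """Terse record builder for tests.

    ``sanger=None`` with ``sanger_negative=False`` means not sequenced;
    ``sanger_negative=True`` means sequenced and negative.
    """
    sex_e = Sex(sex)
    zyg = Zygosity(zygosity) if zygosity else (
        Zygosity.HEMIZYGOUS if sex_e is Sex.MALE else Zygosity.HETEROZYGOUS
    )
    panel_result = (VariantCall(panel_variant, zyg),) if panel_variant else ()
    if sanger is not None:
        sanger_result = (VariantCall(sanger, zyg),)
    elif sanger_negative:
        sanger_result = ()
    else:
        sanger_result = None
    return InfantRecord(
        id=rid,
        sex=sex_e,
        activity_ratio=ratio,
        panel_result=panel_result,
        sanger_result=sanger_result,
    )


def make_cohort(*records: InfantRecord) -> CohortTable:
    return CohortTable(records=tuple(records))


@pytest.fixture(scope="session")
def ref_cohort() -> CohortTable:
    return reference_cohort()
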