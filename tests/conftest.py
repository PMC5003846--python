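import numpy as np
import pandas as pd
import pytest

from cocount import ExpressionMatrix, PanelRun

RCC_TEXT = """\
<Header>
FileVersion,1.7
SoftwareVersion,4.0.0.3
</Header>
<Sample_Attributes>
ID,{sample_id}
Owner,lab
</Sample_Attributes>
<Lane_Attributes>
ID,{sample_id}
FovCount,555
</Lane_Attributes>
<Code_Summary>
CodeClass,Name,Accession,Count
Endogenous,GUSB,NM_000181,250
Endogenous1,MITF,NM_000248,1200
Housekeeping,RPLP0,NM_001002,900
Negative,NEG_A,ERCC_1,4
Negative,NEG_B,ERCC_2,6
Positive,POS_A,ERCC_3,5000
</Code_Summary>
"""


@pytest.fixture
def rcc_file(tmp_path):
    path = tmp_path / "lane1.RCC"
    path.write_text(RCC_TEXT.format(sample_id="lane1"))
    return path


@pytest.fixture
def small_run():
    """3 measured genes x 2 samples plus two negative probes."""
    counts = pd.DataFrame(
        {
            "s1": [110, 40, 900, 8, 12],
            "s2": [220, 80, 1800, 0, 0],
        },
        index=pd.Index(["GENE1", "GENE2", "RPLP0", "NEG_A", "NEG_B"], name="gene"),
    )
    probe_class = pd.Series(
        ["endogenous", "endogenous", "housekeeping", "negative", "negative"],
        index=counts.index,
    )
    samples = pd.DataFrame(
        {"condition": ["untreated", "treated"], "cell_line": ["Me275", "Me275"]},
        index=pd.Index(["s1", "s2"], name="sample_id"),
    )
    return PanelRun(counts=counts, probe_class=probe_class, samples=samples)


@pytest.fixture
def small_expression():
    values = pd.DataFrame(
        np.array(
            [
                [7.3, 7.3, 7.3, 7.3],
                [6.0, 7.0, 6.0, 7.0],
                [5.0, np.nan, 5.2, 5.1],
                [9.0, 9.1, 8.9, 9.0],
                [3.0, 8.0, 3.1, 8.2],
            ]
        ),
        index=pd.Index(["CONST", "ALT", "GAPPY", "TIGHT", "SWING"], name="gene"),
        columns=["a", "b", "c", "d"],
    )
    samples = pd.DataFrame(
        {
            "condition": ["untreated", "treated", "untreated", "treated"],
            "cell_line": ["Me275", "Me275", "Me290", "Me290"],
        },
        index=values.columns,
    )
    return ExpressionMatrix(values=values, samples=samples)
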