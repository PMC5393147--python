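import numpy as np
import pytest

from hypoxamir import ExpressionMatrix, SampleMetadata


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 features x 4 samples, linear scale."""
    values = np.array(
        [
            [100.0, 200.0, 50.0, 80.0],
            [10.0, 20.0, 5.0, 8.0],
            [1.0, 2.0, 4.0, 8.0],
        ]
    )
    return ExpressionMatrix(["f1", "f2", "f3"], ["s1", "s2", "s3", "s4"], values)


def make_metadata(sample_ids, cell_lines, oxygen_pcts, replicates=None, groups=None):
    from hypoxamir.datamodel import oxygen_code_from_pct

    codes = oxygen_code_from_pct(oxygen_pcts)
    replicates = replicates or [1] * len(sample_ids)
    groups = groups or [None] * len(sample_ids)
    return [
        SampleMetadata(
            sample_id=s,
            cell_line=c,
            oxygen_pct=p,
            oxygen_code=code,
            replicate=r,
            group=g,
        )
        for s, c, p, code, r, g in zip(
            sample_ids, cell_lines, oxygen_pcts, codes, replicates, groups
        )
    ]
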