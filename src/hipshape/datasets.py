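"""Published summary data shipped with the package.

These are transcriptions of published summary tables from an adolescent
hip-shape cohort (proximal-femur DXA landmarks scored against an external
adult reference shape model at average ages 14 and 18): the pairwise
Pearson correlation matrices of the first ten hip shape mode scores, and
the image-exclusion cascades that produced the final analysis samples.
They are inputs for the effective-number-of-tests and ledger analyses;
no individual-level data are included.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = [
    "mode_score_correlations",
    "exclusion_stages",
]

# Correlations of the first ten reference-model mode scores, age 14.
_CORR_AGE14 = """\
	HSM1	HSM2	HSM3	HSM4	HSM5	HSM6	HSM7	HSM8	HSM9	HSM10
HSM1	1	0.1853	0.0371	0.0375	0.4698	-0.198	0.1578	-0.272	-0.2019	-0.1227
HSM2	0.1853	1	0.4216	0.131	0.3872	0.0883	0.054	-0.118	0.3098	-0.1471
HSM3	0.0371	0.4216	1	0.2081	0.1451	-0.0381	0.1772	0.144	0.2597	-0.1564
HSM4	0.0375	0.131	0.2081	1	0.0924	-0.1778	0.248	0.1602	0.2208	-0.2277
HSM5	0.4698	0.3872	0.1451	0.0924	1	-0.2271	0.0095	-0.0648	0.3164	-0.0647
HSM6	-0.198	0.0883	-0.0381	-0.1778	-0.2271	1	-0.0972	0.1324	-0.2759	-0.0347
HSM7	0.1578	0.054	0.1772	0.248	0.0095	-0.0972	1	-0.3302	0.2572	0.0019
HSM8	-0.272	-0.118	0.144	0.1602	-0.0648	0.1324	-0.3302	1	-0.191	0.0862
HSM9	-0.2019	0.3098	0.2597	0.2208	0.3164	-0.2759	0.2572	-0.191	1	-0.1126
HSM10	-0.1227	-0.1471	-0.1564	-0.2277	-0.0647	-0.0347	0.0019	0.0862	-0.1126	1
"""

# Correlations of the first ten reference-model mode scores, age 18.
_CORR_AGE18 = """\
	HSM1	HSM2	HSM3	HSM4	HSM5	HSM6	HSM7	HSM8	HSM9	HSM10
HSM1	1	0.141	0.2264	-0.0047	0.4621	-0.2515	0.0537	-0.1779	-0.1618	-0.0226
HSM2	0.141	1	0.3793	0.1983	0.4458	-0.1167	0.1083	-0.1985	0.3159	-0.0712
HSM3	0.2264	0.3793	1	0.4535	0.1827	-0.1872	0.3169	-0.0169	0.0756	-0.1303
HSM4	-0.0047	0.1983	0.4535	1	0.0864	-0.1524	0.1849	0.204	0.1695	-0.2213
HSM5	0.4621	0.4458	0.1827	0.0864	1	-0.3191	0.0347	-0.1862	0.4001	-0.0575
HSM6	-0.2515	-0.1167	-0.1872	-0.1524	-0.3191	1	-0.1257	0.1897	-0.3383	-0.0189
HSM7	0.0537	0.1083	0.3169	0.1849	0.0347	-0.1257	1	-0.1477	0.2756	0.1138
HSM8	-0.1779	-0.1985	-0.0169	0.204	-0.1862	0.1897	-0.1477	1	-0.1628	0.1194
HSM9	-0.1618	0.3159	0.0756	0.1695	0.4001	-0.3383	0.2756	-0.1628	1	-0.0967
HSM10	-0.0226	-0.0712	-0.1303	-0.2213	-0.0575	-0.0189	0.1138	0.1194	-0.0967	1
"""

# Image-exclusion cascades of the two assessment clinics.
_EXCLUSIONS = {
    14: (6162, [
        ("Excluded twins, sibs and re-invites", 171),
        ("Excluded images without genetic or follow-up data", 1255),
        ("Excluded images due to poor image quality", 268),
    ]),
    18: (4746, [
        ("Excluded twins, sibs and re-invites", 115),
        ("Excluded images due to poor image quality", 218),
    ]),
}


def mode_score_correlations(age: int) -> pd.DataFrame:
    """Published 10x10 correlation matrix of the top mode scores.

    ``age`` is 14 or 18 (the two assessment-clinic time points).
    """
    try:
        text = {14: _CORR_AGE14, 18: _CORR_AGE18}[age]
    except KeyError:
        raise ValueError(f"no correlation matrix for age {age}; use 14 or 18")
    return pd.read_csv(io.StringIO(text), sep="\t", index_col=0)


def exclusion_stages(age: int) -> tuple[int, list[tuple[str, int]]]:
    """Published image-exclusion cascade: (initial count, stages)."""
    try:
        initial, stages = _EXCLUSIONS[age]
    except KeyError:
        raise ValueError(f"no exclusion cascade for age {age}; use 14 or 18")
    return initial, list(stages)
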