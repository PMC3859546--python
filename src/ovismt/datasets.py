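"""Bundled small datasets.

`oylum_ancient_genotypes` returns the published genotypes of the 33 ancient
sheep from the Oylum Höyük mound (Kilis, Southeastern Turkey): the observed
base at each of the five diagnostic control-region positions (AF010406
15459, 15476, 15484, 15509, 15512), with '.' meaning "identical to the
reference base", plus the archaeological date range of each sample. These
genotypes are the input for the ancient haplogroup-frequency analysis.

The published haplogroup column is deliberately NOT used by the classifier;
it is retained (column `published_hpg`) only so tests can compare calls
against it.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = ["DIAGNOSTIC_POSITIONS", "DIAGNOSTIC_RULES", "oylum_ancient_genotypes"]

#: Diagnostic control-region positions (1-based, AF010406).
DIAGNOSTIC_POSITIONS = (15459, 15476, 15484, 15509, 15512)

#: Derived (non-reference) bases defining each haplogroup at the diagnostic
#: positions. HPG B is the reference haplogroup: its signature is the
#: reference base at every diagnostic site, hence an empty map. HPG D and
#: the wild O. g. anatolica X haplotype have no published signature in this
#: five-site scheme and ship empty; samples of those lineages fall to
#: "unassigned" unless the user supplies extended rules.
DIAGNOSTIC_RULES: dict[str, dict[int, str]] = {
    "A": {15459: "T", 15484: "A"},
    "B": {},
    "C": {15509: "G"},
    "E": {15476: "C", 15509: "G"},
    "D": {},
    "X": {},
}

# id  15459 15476 15484 15509 15512  published_hpg  date (BCE, early-late)
_OYLUM_TSV = """\
id\tp15459\tp15476\tp15484\tp15509\tp15512\tpublished_hpg\tdate_early\tdate_late
OY003-1\tT\t.\tA\t.\t.\tA\t1800\t1700
OY018-1\tT\t.\tA\t.\t.\tA\t1800\t1700
OY020-1\tT\t.\tA\t.\t.\tA\t1800\t1700
OY024-1\tT\t.\tA\t.\t.\tA\t1800\t1700
OY025-1\tT\t.\tA\t.\t.\tA\t1800\t1700
OY065-2\tT\t.\tA\t.\t.\tA\t1800\t1700
OY010-1\t.\t.\t.\t.\t.\tB\t1800\t1700
OY042-2\t.\t.\t.\t.\t.\tB\t1800\t1700
OY027-1\tT\t.\tA\t.\t.\tA\t1800\t1600
OY134-2\t.\t.\t.\t.\t.\tB\t1800\t1600
OY086-2\t.\t.\t.\t.\t.\tB\t1800\t1600
OY130-2\t.\t.\t.\t.\t.\tB\t1800\t1600
OY044-2\t.\t.\t.\tG\t.\tC\t1800\t1600
OY133-2\tT\t.\tA\t.\t.\tA\t1600\t1200
OY105-2\t.\t.\t.\t.\t.\tB\t1600\t1200
OY067-2\t.\t.\t.\t.\t.\tB\t1600\t1200
OY070-2\tT\t.\tA\t.\t.\tA\t1200\t900
OY061-2\tT\t.\tA\t.\t.\tA\t1200\t900
OY059-2\t.\tC\t.\tG\t.\tE\t1200\t900
OY090-2\tT\t.\tA\t.\t.\tA\t1200\t330
OY123-2\t.\t.\t.\t.\t.\tB\t1200\t330
OY072-2\t.\t.\t.\t.\t.\tB\t1200\t330
OY019-2\t.\t.\t.\tG\t.\tC\t900\t700
OY078-2\tT\t.\tA\t.\t.\tA\t700\t330
OY082-2\tT\t.\tA\t.\t.\tA\t700\t330
OY110-2\tT\t.\tA\t.\t.\tA\t700\t330
OY025-2\tT\t.\tA\t.\t.\tA\t700\t330
OY142-2\tT\tT\tA\tA\tT\tA\t700\t330
OY089-2\t.\t.\t.\t.\t.\tB\t700\t330
OY091-2\t.\t.\t.\t.\t.\tB\t700\t330
OY081-2\t.\t.\t.\t.\t.\tB\t700\t330
OY138-2\t.\t.\t.\t.\t.\tB\t700\t330
OY021-2\t.\t.\t.\t.\t.\tB\t330\t30
"""


def oylum_ancient_genotypes() -> pd.DataFrame:
    """The 33 ancient-sample diagnostic-site genotypes as a DataFrame.

    Columns p15459..p15512 hold the observed base or '.' (= reference);
    date_early/date_late bound the archaeological date in years BCE.
    """
    return pd.read_csv(io.StringIO(_OYLUM_TSV), sep="\t", dtype={"id": str})
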