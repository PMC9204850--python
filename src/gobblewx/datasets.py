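"""Bundled example data.

``aru_survey_rows`` holds season-level verification summaries from a
five-site autonomous-recording-unit gobbling survey in the southeastern
US (2014–2018): candidate detections flagged by an automated detector,
the subset verified as true gobbles, and the effective number of units
recording that season.  These are inputs for the tallying examples and
validation checks; the per-day count series behind them are not bundled.

Note the BFG 2018 season deployed 18 units but the season totals imply 14
effective units (unit failures); the effective count is what is stored,
since it is the divisor behind the per-unit rates.
"""

from __future__ import annotations

import pandas as pd

_ROWS = [
    # site, year, detections, gobbles, effective units
    ("CWMA", 2014, 19214, 14242, 10),
    ("CWMA", 2015, 10614, 6234, 10),
    ("CWMA", 2016, 12458, 7032, 10),
    ("CWMA", 2017, 14941, 10518, 10),
    ("CWMA", 2018, 8246, 3892, 10),
    ("SRS", 2014, 29138, 21484, 20),
    ("SRS", 2015, 22409, 17242, 20),
    ("SRS", 2016, 25039, 18236, 20),
    ("SRS", 2017, 35043, 27366, 20),
    ("SRS", 2018, 16434, 9454, 20),
    ("Webb", 2015, 12476, 8063, 15),
    ("Webb", 2016, 12946, 8305, 15),
    ("Webb", 2017, 9096, 4701, 15),
    ("Webb", 2018, 11793, 5524, 15),
    ("CCWMA", 2017, 5176, 4437, 16),
    ("CCWMA", 2018, 37795, 16606, 36),
    ("BFG", 2017, 15014, 3839, 8),
    ("BFG", 2018, 26404, 7480, 14),
]


def aru_survey_rows() -> pd.DataFrame:
    """Season summaries (18 site-years) of the bundled ARU survey."""
    return pd.DataFrame(
        _ROWS, columns=["site", "year", "detections", "gobbles", "units"]
    )
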