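"""Reference dataset: the published aerosol sample table from the 2015
Imperial Beach surfzone dye-release campaign (three releases, nine
sampling locations, four field blanks, two sampler rinses).

Column notes
------------
``pattern``   whether the sample's EEM showed the tracer fluorescence
              pattern; ``above_lod`` the reported above-detection-limit
              flag (recomputable from ``air_conc_pg_m3`` and the blank
              rows); ``dye_sea_ppb`` the upwind source-water mean, NA for
              night samples with no concurrent sea-surface maps.
``kind``      sample / blank / rinse.

Air concentrations are reported for every sample regardless of the
detection flags (the rendered table puts non-detections in parentheses).
"""
from __future__ import annotations

import io

import numpy as np
import pandas as pd

_CAMPAIGN_CSV = """\
id,release,date,period,site,inland_m,downwind_m,air_volume_m3,pattern,above_lod,air_conc_pg_m3,dye_sea_ppb,kind
1,1,9/23,day,A,615,678,198,Yes,No,14.3,4.4,sample
2,1,9/23,day,B,101,154,135,Yes,Yes,759.0,3.6,sample
3,1,9/23,night,A,615,653,398,No,No,4.8,0.6,sample
4,1,9/24,day,A,615,664,226,No,No,5.2,0.7,sample
5,1,9/24,day,B,101,148,162,Yes,Yes,43.3,0.8,sample
6,1,9/24,night,C,122,,422,No,No,5.0,,sample
7,1,9/24,night,A,615,,377,No,No,11.3,,sample
8,1,9/25,day,C,122,,116,No,No,20.0,,sample
9,1,9/25,day,A,615,,137,No,No,4.8,,sample
10,2,10/8,day,D,976,1057,241,No,No,8.3,0.5,sample
11,2,10/8,day,E,1256,1310,216,No,No,9.4,0.6,sample
12,2,10/8,day,F,3867,3953,181,No,No,8.9,3.4,sample
13,2,10/8,night,E,1256,1284,428,No,No,12.5,0.3,sample
14,2,10/8,day,D,976,1037,54,No,No,20.4,0.3,sample
15,2,10/9,day,G,108,57,140,No,No,9.2,0.4,sample
16,2,10/9,24 h,E,1256,1288,691,No,No,5.3,0.5,sample
17,3,10/12,day,A,615,712,211,No,Yes,44.6,1.8,sample
18,3,10/12,day,H,1193,1275,234,No,No,14.1,2.6,sample
19,3,10/12,day,I,668,720,178,Yes,Yes,184.2,0.6,sample
20,3,10/12,night,H,1193,,347,No,No,15.2,,sample
21,3,10/12,night,A,615,,376,No,No,16.4,1.0,sample
22,3,10/13,day,I,668,694,169,Yes,Yes,55.5,0.1,sample
23,3,10/14,day,I,668,,135,No,Yes,60.9,,sample
24,3,10/15,day,I,668,,152,No,Yes,34.0,,sample
25,blank,10/7,night,D,976,,192,No,,2.0,,blank
26,blank,10/7,night,C,122,,383,No,,7.3,,blank
27,blank,10/7,day,D,976,,119,No,,18.9,,blank
28,blank,10/7,day,C,122,,224,No,,10.0,,blank
29,rinse,9/23,,,,,,No,,,,rinse
30,rinse,10/9,,,,,,No,,,,rinse
"""


def load_field_campaign() -> pd.DataFrame:
    """The campaign aerosol-sample table as a DataFrame.

    Yes/No flags become nullable booleans; NA entries are missing values.
    """
    df = pd.read_csv(io.StringIO(_CAMPAIGN_CSV))
    for col in ("pattern", "above_lod"):
        df[col] = df[col].map({"Yes": True, "No": False}).astype("boolean")
    return df


def field_blank_air_concs() -> np.ndarray:
    """Air concentrations (pg/m^3) of the four field blanks."""
    df = load_field_campaign()
    return df.loc[df["kind"] == "blank", "air_conc_pg_m3"].to_numpy(float)
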