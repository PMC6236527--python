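# Study fixture provenance

`table2_overall.csv` and `table3_seasonal.csv` transcribe the published
per-well concentration summaries for the Ibadan metropolis shallow-groundwater
survey (35 open dug wells, 2016; arsenic, antimony, selenium by ICP-OES).

- `table2_overall.csv` — per-well overall mean, SD and range (min/max) in
  μg/L, pooled over both seasons (n = 6 monthly samples per well).
- `table3_seasonal.csv` — per-well seasonal means and SDs in μg/L
  (wet = May–July, dry = January–March; n = 3 monthly samples each).

Land-use assignment follows the tables' footnote markers: GW1–GW24
residential, GW25–GW29 commercial, GW30–GW33 industrial, GW34–GW35
agricultural. Zeros are below-detection entries, not missing values.

Transcription corrections (documented deviations from the printed tables):

1. GW32 dry-season selenium is printed as "0.026" with no SD. The overall
   GW32 selenium mean of 16.2 μg/L is consistent only with a dry-season mean
   of 26.0 μg/L ((6.33 + 26.0)/2 = 16.17), so the printed value is treated
   as a decimal-shift typo and transcribed as 26.0 with SD recorded as 0
   (unknown).
2. Obvious range typos normalised: GW29 selenium "(8.0–51-0)" → 51.0,
   GW32 arsenic "(0.21.0)" → 0–21.0, GW21 selenium "16.0–64.0)" → 16.0–64.0.

Every other cell is transcribed verbatim. The loader verifies a SHA-256
checksum of both files.
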