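# Data dictionary

All files are plain text. Coordinates are planar miles on the synthetic
study plane unless a haversine workflow supplies (lon, lat) degrees.

## `tracts.csv` — one row per census tract

| column | type | description |
|---|---|---|
| `tract_id` | string(11) | fixed-width tract identifier (GEOID-style) |
| `population` | int > 0 | total resident population |
| `area` | float > 0 | land area, square miles |
| `x`, `y` | float | tract representative point (centroid of its square) |
| `prop_poverty` | float [0,1] | share of population below the Federal poverty level |
| `median_income` | float or empty | median household income, dollars; empty = missing (tract excluded from the analytic cohort) |
| `msa_id` | string | metropolitan statistical area the tract belongs to |
| `msa_median_income` | float | median household income of that MSA, dollars |
| `prop_white`, `prop_black`, `prop_hispanic`, `prop_asian`, `prop_aian` | float [0,1] | race/ethnicity shares; remainder = other/multiracial |
| `prop_age65` | float [0,1] | share aged 65+ |
| `prop_female` | float [0,1] | female share |
| `prop_lt_hs` | float [0,1] | share with less than high-school education |
| `prop_uninsured` | float [0,1] | share without health insurance |
| `prop_amb_disability` | float [0,1] | share with an ambulatory disability |
| `vehicles_owned` | int ≥ 0 | individuals owning a car (drives the 0.5-mile low-access exception when < 100) |
| `ddi` | float [0,100] | digital divide index (higher = worse technology availability) |
| `ddi_infa` | float [0,100] | DDI infrastructure/adoption component |
| `ddi_se` | float [0,100] | DDI socioeconomic component |
| `rri` | float > 0 or empty | residential redlining index (mortgage-denial odds ratio vs the MSA); empty = missing, retained as its own category |

## `blocks.csv` — one row per census block

| column | type | description |
|---|---|---|
| `block_id` | string | unique block identifier (`<tract_id>B<nnn>`) |
| `tract_id` | string(11) | parent tract; every tract has ≥ 1 block |
| `x`, `y` | float | block centroid |
| `population` | int ≥ 0 | block population; blocks of one tract sum exactly to the tract population |

## `pharmacies.geojson`

RFC 7946 `FeatureCollection` of `Point` features. Properties: `pharmacy_id`
(string), `open` (boolean; closed pharmacies are excluded from all distance
computations). Any conforming point FeatureCollection is accepted as input.

## `truth.json`

Geometry mode: `{"mode": "geometry", "per_tract": {tract_id: {"desert",
"desert_distance_only", "low_income", "low_access", "radius_used"} |
{"excluded": reason}}}` — labels computed by the generator's exhaustive
block–pharmacy distance scan.

Label mode: `{"mode": "label", "true_log_odds": {...}, "desert":
{tract_id: bool}}` — the generating coefficient vector and drawn labels.

## `assessments.csv` — classifier output, one row per analytic tract

`tract_id, urbanicity, low_income, low_access, desert,
desert_distance_only, access_fraction_beyond, radius_used, segregation,
ddi_category, redlining_category` (stable column order).
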