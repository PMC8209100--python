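# File schemas

All tabular files are comma-separated text with a header row; all
geographic layers are GeoJSON (RFC 7946) FeatureCollections in WGS84.
Units are stated per column; timestamps are UTC ISO-8601.

## Ping stream (`pings.csv`)

| column | type | notes |
|---|---|---|
| `user_id` | string | opaque anonymized device id |
| `timestamp_utc` | ISO-8601 | seconds resolution, UTC (`Z` suffix) |
| `lat` | degrees | WGS84, −90..90 |
| `lon` | degrees | WGS84, −180..180 |
| `accuracy_m` | meters | reported horizontal accuracy; may be empty |

Rows with unparseable coordinates/timestamps are dropped on read (count
logged); duplicate `(user_id, timestamp)` rows keep the first.

## Road layer (`roads.geojson`)

LineString features; properties `segment_id` (string) and `highway`
(road class).  Classes `secondary, tertiary, residential, living_street,
pedestrian, footway, track, path` are pedestrian-eligible; everything
else (motorway, trunk, ...) is excluded from walkable space.

## Park layer (`parks.geojson`)

Polygon features; property `park_id`.

## POI layer (`pois.geojson`)

Point features; properties `poi_id` and `category` (e.g. food, service,
transportation, shopping, school, health, coffee/tea, work, outdoors,
city/outdoors).

## Tract layer (`tracts.geojson`)

Polygon features; properties `tract_id` and `msa_id`.

## Tract attributes (`tract_attributes.csv`)

| column | type | notes |
|---|---|---|
| `tract_id` | string | unique |
| `msa_id` | string | metropolitan statistical area |
| `median_income` | currency | |
| `frac_black` | proportion | in [0, 1] |
| `frac_public_transit` | proportion | in [0, 1] |
| `frac_over64` | proportion | in [0, 1] |
| `park_access` | score | higher = better access |
| `obesity_prev` | proportion | in [0, 1] |
| `population` | count | ≥ 0 |

## Ground truth (`ground_truth.csv`, synthetic runs only)

One row per planted segment: `segment_id`, `user_id`, `kind`
(`walk_utilitarian | walk_leisure | drive | stationary`), `t_start`,
`t_end` (UTC), `planted_length_m` (meters), `dest_category` (POI
category or empty), `day_index`, `home_tract`.

## Bout table (`bouts.csv` / `bouts_labeled.csv`)

| column | type | notes |
|---|---|---|
| `bout_id` | string | |
| `user_id` | string | |
| `start_t`, `end_t` | ISO-8601 UTC | first/last ping of the bout |
| `n_pings` | count | |
| `distance_m` | meters | sum of consecutive great-circle gaps |
| `duration_min` | minutes | |
| `end_lat`, `end_lon` | degrees | final ping (the destination probe) |
| `date` | date | local calendar day of the bout start |
| `purpose` | string | `utilitarian` or `leisure` (after classification) |
| `destination_category` | string | matched POI category or empty |

## Per-user-day summaries (`user_day_summaries.csv`)

One row per (active user, local date), zero-walking days included:
`user_id`, `home_tract`, `date`, `weight` (post-stratification, mean 1),
`n_bouts_total/utilitarian/leisure` (counts), `distance_m_total/
utilitarian/leisure` (meters), `minutes_total` (minutes).
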