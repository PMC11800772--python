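# JSON document formats

All on-disk artifacts are versioned JSON; every document carries a
`format` tag and an integer `version`, and loaders reject unknown
versions explicitly.

## Factor graph — `rcnbp-factor-graph`, version 1

```json
{
 "format": "rcnbp-factor-graph",
 "version": 1,
 "variables": [{"id": "x", "cardinality": 2, "kind_label": "feature"}],
 "factors": [
  {"id": "u", "factor_kind": "TABLE", "neighbor_ids": ["x"],
   "params": {"log_potential": {"__array__": [0.0, -1.0]}}}
 ]
}
```

`factor_kind` is one of `TABLE`, `OR`, `POOL`, `EDGE_APPEARANCE`,
`CHANNEL`.  Neighbor role order is fixed per kind: OR `(c1..cM, e)`,
POOL `(a, b1..bM)`, EDGE_APPEARANCE `(a, b, e)`, CHANNEL
`(source, pixel)`.  Kind-specific params: `log_potential` (TABLE /
CHANNEL; numeric arrays are wrapped as `{"__array__": ...}`),
`c_penalty` (EDGE_APPEARANCE, > 0), `precision` / `sensitivity`
(CHANNEL).  Log-potentials are in nats; `-inf` is replaced by the
sentinel `-1e9` on load.

## RCN model — `rcnbp-model`, version 1

Top-level keys: `config` (grid shape, pooling/lateral radii, appearance
cardinality, discontinuity penalty, channel parameters, priors,
`include_surface`, `n_parts`, `tie_epsilon`), `templates` (per name:
`strokes` as ordered `[row, col, orientation]` cell lists with a
`closed` flag, `interior` cells, `color_bin`), `features` (per id:
`level`, `children` pool ids, `prior_llr`), `pools` (per id: `level`,
`center`, `members` as `[unit_id, shift_tag]` pairs), `laterals`
(pool pair, allowed `[tag_i, tag_j]` member pairs, `clone_tag`),
`surface` (shape, `appearance_n`, `c_penalty`, or null) and
`occluders` (template names).  Orientations are degrees in
{0, 45, 90, 135}; coordinates are 0-based row-major.  Loading validates
referential integrity (dangling pool members or child pools are
reported by path).

## Stimulus — `rcnbp-stimulus`, version 1

`contour`: nested list `[rows][cols][4]` of contour log-likelihood
ratios per orientation; `appearance`: `[rows][cols]` of color-bin
integers with `-1` = unobserved; `provenance`: generator name,
parameters and seed.

## Traces — JSON-lines

Engine traces (one record per update group): `iteration`, `group`,
`max_delta`, optional `beliefs`.  Parse-stage traces (one record per
protocol stage): `stage` (FWD_FEAT, FWD_LAT, FWD_POOL, SELECT,
BWD_UNPOOL, BWD_LAT, EXPLAIN_AWAY, SURFACE_FILL), `pass`, `anatomy`
(annotation string), `beliefs` (binary LLR per recorded variable).

## Experiment reports

`rcn experiment <name>` writes `<name>.json` (`config` + `metrics`),
one CSV per table, and for the occlusion battery an accuracy-curve PNG.
All are regenerable bit-identically from config + seed.
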