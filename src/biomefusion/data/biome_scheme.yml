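# Default 16-biome threshold scheme.
#
# Each biome is a box of per-variable intervals [lo, hi): closed on the
# lower bound, open on the upper, so every attainable six-tuple of
# (fpc, height, evergreen, tropical, temperate, gdd) falls in exactly one
# biome.  `null` means unbounded on that side.  Interval endpoints may
# name an entry of `thresholds`, which is what makes the scheme scalable
# for threshold-sensitivity experiments: replacing a threshold value
# rewrites every interval that references it.
#
# Structure: total vegetation cover (fpc) separates arid (< fpc_arid),
# grass/shrub (fpc_arid..fpc_forest) and wooded (>= fpc_forest) land;
# within wooded land, height separates savanna (< h_savanna),
# woodland/tall savanna (h_savanna..h_forest) and forest (>= h_forest).
# Composition (tropical / temperate dominance at 0.5 of vegetation,
# evergreen vs deciduous at 0.5) and growing degree days split the
# forest and savanna classes into the named biomes.

thresholds:
  fpc_arid: 0.3        # desert/shrub vs grass-savanna cover boundary
  fpc_forest: 0.6      # grass vs forest/savanna cover boundary
  h_savanna: 5.0       # m; savanna vs woodland/tall-savanna height
  h_forest: 10.0       # m; woodland/tall-savanna vs forest height
  h_max: 130.0         # m; hydrological limit of tree height
  eg_split: 0.5        # evergreen vs deciduous fraction of vegetation
  trop_dom: 0.5        # tropical fraction needed for tropical dominance
  temp_dom: 0.5        # temperate fraction needed for temperate dominance
  gdd_cold: 900.0      # degC day; cold limit (tundra / shrub-tundra side)
  gdd_sclero: 2000.0   # degC day; sclerophyll woodland warmth requirement
  gdd_warm: 5000.0     # degC day; warm-temperate forest warmth requirement

biomes:
  # --- forests: fpc >= fpc_forest, h_forest <= height < h_max ---------
  - code: Thf
    name: tropical humid forest
    intervals:
      fpc: [fpc_forest, null]
      height: [h_forest, h_max]
      tropical: [trop_dom, null]
      evergreen: [eg_split, null]
  - code: Tdf
    name: tropical dry forest
    intervals:
      fpc: [fpc_forest, null]
      height: [h_forest, h_max]
      tropical: [trop_dom, null]
      evergreen: [null, eg_split]
  - code: wtf
    name: warm temperate forest
    intervals:
      fpc: [fpc_forest, null]
      height: [h_forest, h_max]
      tropical: [null, trop_dom]
      temperate: [temp_dom, null]
      gdd: [gdd_warm, null]
  - code: tef
    name: temperate evergreen forest
    intervals:
      fpc: [fpc_forest, null]
      height: [h_forest, h_max]
      tropical: [null, trop_dom]
      temperate: [temp_dom, null]
      gdd: [null, gdd_warm]
      evergreen: [eg_split, null]
  - code: tdf
    name: temperate deciduous forest
    intervals:
      fpc: [fpc_forest, null]
      height: [h_forest, h_max]
      tropical: [null, trop_dom]
      temperate: [temp_dom, null]
      gdd: [null, gdd_warm]
      evergreen: [null, eg_split]
  - code: bef
    name: boreal evergreen forest
    intervals:
      fpc: [fpc_forest, null]
      height: [h_forest, h_max]
      tropical: [null, trop_dom]
      temperate: [null, temp_dom]
      evergreen: [eg_split, null]
  - code: bdf
    name: boreal deciduous forest
    intervals:
      fpc: [fpc_forest, null]
      height: [h_forest, h_max]
      tropical: [null, trop_dom]
      temperate: [null, temp_dom]
      evergreen: [null, eg_split]

  # --- woodland/tall savanna ecotone ----------------------------------
  - code: WTs
    name: woodland/tall savanna
    intervals:
      fpc: [fpc_forest, null]
      height: [h_savanna, h_forest]

  # --- savannas and parklands: fpc >= fpc_forest, height < h_savanna --
  - code: Ts
    name: tropical savanna
    intervals:
      fpc: [fpc_forest, null]
      height: [null, h_savanna]
      tropical: [trop_dom, null]
  - code: sw
    name: sclerophyll woodland
    intervals:
      fpc: [fpc_forest, null]
      height: [null, h_savanna]
      tropical: [null, trop_dom]
      temperate: [temp_dom, null]
      gdd: [gdd_sclero, null]
  - code: tp
    name: temperate parkland
    intervals:
      fpc: [fpc_forest, null]
      height: [null, h_savanna]
      tropical: [null, trop_dom]
      temperate: [temp_dom, null]
      gdd: [null, gdd_sclero]
  - code: bp
    name: boreal parkland
    intervals:
      fpc: [fpc_forest, null]
      height: [null, h_savanna]
      tropical: [null, trop_dom]
      temperate: [null, temp_dom]

  # --- open grass/shrubland: fpc_arid <= fpc < fpc_forest --------------
  - code: dg
    name: dry grass/shrubland
    intervals:
      fpc: [fpc_arid, fpc_forest]
      gdd: [gdd_cold, null]
  - code: st
    name: shrub tundra
    intervals:
      fpc: [fpc_arid, fpc_forest]
      gdd: [null, gdd_cold]

  # --- sparse/arid: fpc < fpc_arid ------------------------------------
  - code: hd
    name: hot desert
    intervals:
      fpc: [null, fpc_arid]
      gdd: [gdd_cold, null]
  - code: t
    name: tundra
    intervals:
      fpc: [null, fpc_arid]
      gdd: [null, gdd_cold]
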