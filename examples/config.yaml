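# Example run configuration for the pathfractal CLI.
# `pathfractal simulate|estimate|analyze --config examples/config.yaml ...`

simulate:
  n_per_cell: 15        # specimens per family x treatment cell
  n_frames: 15000       # 600 s at 25 fps
  fps: 25.0
  seed: 1
  sigma_site: 0.15      # site random-intercept SD on log-kappa
  buffer_complex: 0.8   # attenuation of the thermal effect in boulders/macrophytes

estimate:
  resolution: 256       # raster grid side
  seg_len: 1500         # frames per analysis segment
  aggregate: mean       # or "whole"
  max_missing: 0.1      # exclusion threshold for gappy segments
  smoothing_window: 1   # odd; >1 median-smooths speeds before MSR

analyze:
  alpha: 0.05
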