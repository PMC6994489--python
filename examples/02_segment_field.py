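"""Segment nuclei and build dilated per-cell masks on a synthetic field.

Shows the two thresholds at work: Otsu (conservative, seeds the nuclei)
and Rosin (permissive, below Otsu, defines the cell territory that is then
dilated and partitioned among the seeds).
"""

import traquant as tq

spec = tq.FieldSpec(height_px=384, width_px=384, n_cells=80, rng_seed=4)
field, truth = tq.generate_field(spec)

prep = tq.preprocess_dapi(field.dapi)
t_otsu = tq.otsu_threshold(prep)
t_rosin = tq.rosin_threshold(prep)
seeds = tq.segment_nuclei(prep)
cells = tq.dilated_cell_mask(prep, seeds)

matched = len({seeds.labels[c.center] for c in truth} - {0})
print(f"thresholds on preprocessed DAPI: Otsu {t_otsu:.1f} AU, "
      f"Rosin {t_rosin:.1f} AU (Rosin < Otsu as expected)")
print(f"{seeds.n_labels} nuclei segmented from {len(truth)} rendered "
      f"({matched} truth centres matched one-to-one)")
print(f"mean nucleus area {seeds.areas_px.mean():.0f} px, "
      f"mean cell-mask area {cells.areas_px.mean():.0f} px "
      f"(the dilated mask captures the surface staining around each nucleus)")
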