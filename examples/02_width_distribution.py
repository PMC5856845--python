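"""Width-frequency distributions and the mid-width dropout of neuropathy.

Builds a healthy cohort of phantoms and a severely degraded one (the
neuropathy operator removes bundles preferentially around the normal
mean width ~3.2 µm), then compares their normalized width histograms.
"""

import ccmorph as cm
from ccmorph.morphometry import analyze_mask
from ccmorph.widths import average_distributions, fit_width_model, midwidth_dropout

def cohort_distribution(severity: float, n: int = 8):
    dists = []
    for s in range(n):
        spec = cm.random_plexus(seed=100 + s)
        spec = cm.apply_neuropathy(spec, severity)
        img, _ = cm.generate_plexus(spec)
        _, _, wp = analyze_mask(cm.segment_nerves(img))
        if len(wp.widths_px):
            dists.append(cm.width_histogram(wp))
    return average_distributions(dists)

healthy = cohort_distribution(0.0)
severe = cohort_distribution(1.0)

fit = fit_width_model(healthy, "gaussian")
print("healthy width peak (Gaussian fit): "
      f"{fit.location:.2f} um (scale {fit.scale:.2f} um)")

ratio = midwidth_dropout(severe, healthy, band_um=(2.8, 4.0))
print(f"2.8-4.0 um band mass, severe vs healthy: {100 * ratio:.0f}%")

# A healthy plexus peaks near 3.1-3.2 µm.  Under severe neuropathy the
# mid-width band is depleted (ratio well below 100%) while thin and
# thick bundles are relatively preserved — the characteristic dropout
# signature this package quantifies.
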