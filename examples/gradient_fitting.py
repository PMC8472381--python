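"""Estimate a taxon's labeling level from its two-bottle density shift.

Builds a small noiseless DNA-versus-density profile for one taxon in the
control and labeled bottles, fits a Gaussian in each, and converts the
peak shift to an atom fraction of heavy carbon (shift / 0.036 g/mL).
"""

import numpy as np

from phagesip import fit_density_gaussian, labeling_level, theoretical_density

densities = np.linspace(1.65, 1.78, 12)


def profile(mu, amplitude=5.0, sigma=0.006):
    return amplitude * np.exp(-((densities - mu) ** 2) / (2 * sigma**2))


fit_control = fit_density_gaussian(densities, profile(1.716))
fit_labeled = fit_density_gaussian(densities, profile(1.746))
print(f"control-bottle peak: {fit_control.mean_density:.4f} g/mL "
      f"(R^2 = {fit_control.r_squared:.3f})")
print(f"labeled-bottle peak: {fit_labeled.mean_density:.4f} g/mL "
      f"(R^2 = {fit_labeled.r_squared:.3f})")

result = labeling_level(fit_control.mean_density, fit_labeled.mean_density)
print(f"labeling: {100 * result.labeling:.0f}% of the taxon's DNA carbon is "
      f"heavy (flag: {result.flag})")

# When the control bottle is too sparse to fit, GC content predicts the
# unlabeled density instead (Schildkraut relation).
gc = 0.57
print(f"GC fallback: a genome at {100 * gc:.0f}% GC bands at "
      f"{theoretical_density(gc):.4f} g/mL unlabeled")
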