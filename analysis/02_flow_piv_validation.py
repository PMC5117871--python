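#!/usr/bin/env python
"""Validate the flow pipeline against imposed synthetic flows.

Advects a synthetic meshwork under a known Gaussian-bump flow, recovers
the field by PIV, reduces it to an AP velocity profile and a compression
rate, and fits the erf onset model to a synthetic velocity time course.

Writes results/flow_validation.json.
"""

import json
from pathlib import Path

import numpy as np
from scipy.ndimage import shift as nd_shift
from scipy.special import erf

from nemacortex.flow import compression_rate, fit_onset_time, piv, velocity_profile
from nemacortex.synth import (
    FlowProfileSpec,
    MeshworkParams,
    advect_image,
    generate_filament_image,
    generate_flow_profile,
)

OUT = Path(__file__).resolve().parents[1] / "results"
PIXEL = 0.1  # um/px
DT_S = 2.0
PX_PER_FRAME = PIXEL / (DT_S / 60.0)


def main() -> None:
    img = generate_filament_image(MeshworkParams(bias_B=0.5, seed=7, snr=20))

    shifted = nd_shift(img, (0, 3.0), order=3, mode="nearest")
    vmap = piv(img, shifted, dt=DT_S, pixel_size=PIXEL)
    uniform_err = float(np.max(np.abs(vmap.vx / PX_PER_FRAME - 3.0)))

    field = generate_flow_profile(
        FlowProfileSpec(shape="gaussian_bump", peak_velocity=-5.0, width=4.33,
                        grid=np.linspace(-15, 15, 201))
    )
    advected = advect_image(img, field, DT_S / 60.0, PIXEL)
    vmap = piv(img, advected, dt=DT_S, pixel_size=PIXEL)
    imposed = field.v_at(vmap.x_um) * (DT_S / 60.0) / PIXEL
    rms_err = float(np.sqrt(np.mean((vmap.vx / PX_PER_FRAME - imposed) ** 2)))

    x_prof, v_prof = velocity_profile(vmap)
    rate = compression_rate(x_prof, v_prof, smooth_sigma=2.0)
    peak_rate = float(np.nanmax(rate))

    t = np.linspace(-4, 8, 40)
    rng = np.random.default_rng(5)
    v_t = 1 + 2 * erf((t - 2.0) / 1.5)
    onset = fit_onset_time(t, v_t + rng.normal(0, 0.05 * np.ptp(v_t), t.size))

    results = {
        "uniform_shift_max_error_px": uniform_err,
        "nonuniform_flow_rms_error_px": rms_err,
        "piv_peak_compression_per_min": peak_rate,
        "imposed_peak_compression_per_min": float((-field.dvdx).max()),
        "onset_t0_recovered_min": onset.t0,
        "onset_t0_true_min": 2.0,
    }
    OUT.mkdir(exist_ok=True)
    (OUT / "flow_validation.json").write_text(json.dumps(results, indent=2))
    print(json.dumps(results, indent=2))
    print(
        f"\nPIV recovers a 3 px uniform shift to {uniform_err:.3f} px and the "
        f"imposed compressive flow to {rms_err:.3f} px RMS; the measured "
        f"compression peak is {peak_rate:.2f}/min against the imposed "
        f"{(-field.dvdx).max():.2f}/min; onset recovered at "
        f"t0 = {onset.t0:.2f} min (truth 2.00)."
    )


if __name__ == "__main__":
    main()
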