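#!/usr/bin/env python
"""Linear stability of the baseline activator-inhibitor kinetics.

Solves the homogeneous steady state, checks that it is stable to uniform
perturbations yet destabilized by diffusion (the Turing mechanism), and
writes the dispersion relation.  Outputs: results/stability.json and
results/dispersion.png.
"""

from pathlib import Path

import numpy as np

from denticle_rd.io import save_json
from denticle_rd.kinetics import catshark_params, growth_rate, turing_check
from denticle_rd.presets import little_skate_params, thornback_params

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    report = {}
    for name, params in [("catshark", catshark_params()),
                         ("thornback", thornback_params()),
                         ("little_skate", little_skate_params())]:
        rep = turing_check(params)
        report[name] = {
            "u_star": rep.u_star, "v_star": rep.v_star,
            "trace": rep.trace, "determinant": rep.determinant,
            "stable_without_diffusion": rep.stable_without_diffusion,
            "turing_unstable": rep.turing_unstable,
            "k2_range": rep.k2_range,
        }
        lo, hi = rep.k2_range
        k2 = np.linspace(0, 1.5 * hi, 2000)
        peak = k2[np.argmax(growth_rate(params, k2))]
        report[name]["fastest_wavelength"] = 2 * np.pi / np.sqrt(peak)
        print(f"{name}: steady state ({rep.u_star:.4f}, {rep.v_star:.4f}), "
              f"tr={rep.trace:.4g}, det={rep.determinant:.4g}, "
              f"Turing unstable={rep.turing_unstable}, "
              f"fastest wavelength={report[name]['fastest_wavelength']:.2f}")

    save_json(report, OUT / "stability.json")

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(6, 4))
    k2 = np.linspace(0, 3, 2000)
    for name, params in [("catshark", catshark_params()),
                         ("thornback", thornback_params()),
                         ("little_skate", little_skate_params())]:
        ax.plot(k2, growth_rate(params, k2), label=name)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel(r"$k^2$")
    ax.set_ylabel("growth rate")
    ax.legend()
    fig.tight_layout()
    fig.savefig(OUT / "dispersion.png", dpi=120)
    print(f"wrote {OUT / 'stability.json'} and {OUT / 'dispersion.png'}")


if __name__ == "__main__":
    main()
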