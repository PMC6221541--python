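"""Named presets binding kinetics, grid and initiator geometry.

Four regimes are provided:

* ``catshark`` — the dense baseline: printed kinetic constants, L = 75,
  T = 1500, n = 128, six initiator spots of radius 4.5 seeded at u0 = 5.
* ``catshark_gap`` — identical, with the third initiator spot ablated.
* ``thornback`` — a sparser, thornback-skate-like regime: inhibitor
  degradation d_v and ceiling G_max lowered, inhibitor diffusivity D_v
  raised, on the three-spot skate initiator row.  The concrete values are a
  calibration within those stated directions, not printed constants; many
  alternative combinations give similar patterns.
* ``little_skate`` — the thornback regime with the activator constitutive
  production c_u additionally lowered, further reducing coverage density.

dt is always re-derived from dt = dx^2/(8 max(D_u, D_v)), so raising D_v
automatically shrinks the step.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

from .grid_solver import GridSpec
from .initiators import SpotConfig, catshark_config, gap_config, skate_config
from .kinetics import KineticParams, catshark_params

__all__ = ["Preset", "get_preset", "preset_names",
           "thornback_params", "little_skate_params"]


def thornback_params() -> KineticParams:
    """Calibrated sparser regime: d_v 0.08->0.06, G_max 0.5->0.3,
    D_v 0.6->1.0 relative to the catshark set."""
    return catshark_params().replace(d_v=0.06, G_max=0.3, D_v=1.0)


def little_skate_params() -> KineticParams:
    """Thornback regime with c_u 0.04->0.02."""
    return thornback_params().replace(c_u=0.02)


@dataclass(frozen=True)
class Preset:
    """A complete, reproducible experiment definition."""

    name: str
    params: KineticParams
    grid: GridSpec
    spots: SpotConfig
    threshold_fraction: float = 0.5
    window_radius: float | None = None   # None -> 1.5 * R_spot at analysis
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "params": self.params.to_dict(),
            "grid": {"L": self.grid.L, "n": self.grid.n,
                     "dt": self.grid.dt, "T": self.grid.T},
            "spots": self.spots.to_dict(),
            "threshold_fraction": self.threshold_fraction,
            "window_radius": self.window_radius,
            "note": self.note,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Preset":
        return cls(
            name=d["name"],
            params=KineticParams.from_dict(d["params"]),
            grid=GridSpec(**{k: d["grid"][k] for k in ("L", "n", "dt", "T")}),
            spots=SpotConfig.from_dict(d["spots"]),
            threshold_fraction=float(d.get("threshold_fraction", 0.5)),
            window_radius=d.get("window_radius"),
            note=d.get("note", ""),
        )

    def with_overrides(self, overrides: dict) -> "Preset":
        """Apply flat key=value overrides.

        Keys resolve to kinetic constants (a_u ... D_v), grid fields
        (L, n, T, dt), spot fields (R_spot, n_spot, u0, centers,
        removed_indices) or analysis options (threshold_fraction,
        window_radius).  Changing L, n or a diffusivity re-derives dt from
        the stability rule unless dt itself is overridden.
        """
        if not overrides:
            return self
        kin_keys = set(self.params.to_dict())
        grid_keys = {"L", "n", "T", "dt"}
        spot_keys = {"R_spot", "n_spot", "u0", "centers", "removed_indices"}
        ana_keys = {"threshold_fraction", "window_radius"}
        unknown = set(overrides) - kin_keys - grid_keys - spot_keys - ana_keys
        if unknown:
            raise KeyError(f"unknown override keys: {sorted(unknown)}")

        params = self.params
        kin_over = {k: float(v) for k, v in overrides.items() if k in kin_keys}
        if kin_over:
            params = params.replace(**kin_over)

        L = float(overrides.get("L", self.grid.L))
        n = int(overrides.get("n", self.grid.n))
        T = float(overrides.get("T", self.grid.T))
        if "dt" in overrides:
            grid = GridSpec(L=L, n=n, T=T, dt=float(overrides["dt"]))
        elif kin_over.keys() & {"D_u", "D_v"} or {"L", "n"} & overrides.keys():
            grid = GridSpec.for_params(params, L=L, n=n, T=T)
        else:
            grid = GridSpec(L=L, n=n, T=T, dt=self.grid.dt)

        spot_over = {k: v for k, v in overrides.items() if k in spot_keys}
        spots = self.spots.replace(**spot_over) if spot_over else self.spots

        return dc_replace(
            self, params=params, grid=grid, spots=spots,
            threshold_fraction=float(overrides.get("threshold_fraction",
                                                   self.threshold_fraction)),
            window_radius=overrides.get("window_radius", self.window_radius),
        )


def _build() -> dict[str, Preset]:
    cp = catshark_params()
    cat_grid = GridSpec.for_params(cp)
    tp = thornback_params()
    lp = little_skate_params()
    return {
        "catshark": Preset(
            name="catshark", params=cp, grid=cat_grid,
            spots=catshark_config(),
            note="dense baseline; printed parameter set"),
        "catshark_gap": Preset(
            name="catshark_gap", params=cp, grid=cat_grid,
            spots=gap_config(),
            note="baseline with third initiator spot ablated"),
        "thornback": Preset(
            name="thornback", params=tp,
            grid=GridSpec.for_params(tp), spots=skate_config(),
            note="sparser regime; d_v/G_max down, D_v up "
                 "(calibrated values, not printed constants)"),
        "little_skate": Preset(
            name="little_skate", params=lp,
            grid=GridSpec.for_params(lp), spots=skate_config(),
            note="sparsest regime; thornback plus c_u down "
                 "(calibrated values, not printed constants)"),
    }


_PRESETS = _build()


def preset_names() -> list[str]:
    return list(_PRESETS)


def get_preset(name: str) -> Preset:
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; "
                       f"available: {preset_names()}") from None
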