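"""End-to-end planning: model and results objects, OR-instruction rendering.

:class:`FenestrationPlanner` bundles the anatomy (centerline + ostia), the
chosen graft template and the numerical settings; its :meth:`fit` runs the
full pipeline — deployed-diameter sizing, graft/fenestration mask
generation, alignment search (with posterior-relaxation fallback), graft
lofting, harmonic flattening, and barycentric mapping of the fitted design
back to 3D — and returns a :class:`FenestrationPlan` carrying the fitted
offsets, per-vessel deviations and the artifacts needed for the
operating-room instruction sheet and the 3D overlay.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import anatomy, meshing, parameterize, search, templates, texture
from .errors import InputError

logger = logging.getLogger("fenplan")

__all__ = ["FenestrationPlanner", "FenestrationPlan", "render_instructions"]

DEFAULTS = dict(resolution=0.25, margin=1.0, n_circ=96, axial_spacing=1.0,
                max_posterior_shift=3.0)


class FenestrationPlanner:
    """Patient-specific fenestration planning model.

    Parameters
    ----------
    centerline
        :class:`~fenplan.anatomy.Centerline` of the aortic lumen.
    ostia
        List of dicts with keys ``vessel``, ``point`` (3D mm), ``diameter``,
        ``prioritized`` (as returned by :func:`fenplan.anatomy.load_ostia`).
    template
        :class:`~fenplan.templates.GraftTemplate` selected by the surgeon.
    graft_top_station
        Proximal landing position, mm of centerline arclength.  Pass
        ``graft_top_point`` (a 3D point, projected onto the centerline)
        instead when the landing position is picked on the image — this is
        robust to where the extracted centerline happens to start.
    datum
        Reference direction for phi = 0 (default: patient-anterior +y).
    """

    def __init__(self, centerline, ostia, template, *, graft_top_station=None,
                 graft_top_point=None, datum=(0.0, 1.0, 0.0), resolution=None,
                 margin=None, n_circ=None, axial_spacing=None,
                 max_posterior_shift=None, posterior_sign=None):
        self.centerline = centerline
        self.ostia = ostia
        self.template = template
        if graft_top_point is not None:
            graft_top_station = centerline.project(np.asarray(graft_top_point, float))
        if graft_top_station is None:
            raise InputError("provide graft_top_station or graft_top_point")
        self.graft_top_station = float(graft_top_station)
        self.datum = np.asarray(datum, dtype=float)
        self.resolution = resolution if resolution is not None else DEFAULTS["resolution"]
        self.margin = margin if margin is not None else DEFAULTS["margin"]
        self.n_circ = n_circ if n_circ is not None else DEFAULTS["n_circ"]
        self.axial_spacing = axial_spacing if axial_spacing is not None else DEFAULTS["axial_spacing"]
        self.max_posterior_shift = (max_posterior_shift if max_posterior_shift is not None
                                    else DEFAULTS["max_posterior_shift"])
        self.posterior_sign = posterior_sign

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_labelmap(cls, labelmap, spacing, ostia, template, **kw):
        """Build from a binary lumen volume (array + spacing) or NIfTI path."""
        if isinstance(labelmap, (str, Path)):
            labelmap, spacing = anatomy.load_labelmap(labelmap)
        if isinstance(ostia, (str, Path)):
            ostia = anatomy.load_ostia(ostia)
        cl = anatomy.compute_centerline(labelmap, spacing)
        return cls(cl, ostia, template, **kw)

    @classmethod
    def from_synthetic(cls, case, template=None, **kw):
        """Build from a :class:`~fenplan.synthetic.SyntheticCase`."""
        if template is None:
            template = templates.load_repository()[case.template_name]
        if "graft_top_station" not in kw:
            kw.setdefault("graft_top_point", case.graft_top_point)
        kw.setdefault("datum", case.datum)
        cl = anatomy.compute_centerline(case.labelmap, case.spacing)
        return cls(cl, case.ostia, template, **kw)

    @classmethod
    def from_config(cls, config: dict | str | Path):
        """Build from a YAML/JSON config file or dict (CLI entry path)."""
        if isinstance(config, (str, Path)):
            import yaml
            config = yaml.safe_load(Path(config).read_text())
        tname = config.get("template")
        repo = templates.load_repository(config.get("template_repository"))
        if isinstance(tname, dict):
            template = templates.make_template(tname)
        elif tname in repo:
            template = repo[tname]
        else:
            raise InputError(f"unknown template {tname!r}")
        kw = {k: config[k] for k in ("resolution", "margin", "n_circ",
                                     "axial_spacing", "max_posterior_shift")
              if k in config}
        if "datum" in config:
            kw["datum"] = config["datum"]
        if "graft_top_point" in config:
            kw["graft_top_point"] = config["graft_top_point"]
        else:
            kw["graft_top_station"] = config["graft_top_station"]
        return cls.from_labelmap(config["labelmap"], None, config["ostia"],
                                 template, **kw)

    # -- fitting ----------------------------------------------------------
    def fit(self, *, force_map: bool = False) -> "FenestrationPlan":
        """Run the full planning pipeline and return the results object."""
        timings = {}
        t0 = time.perf_counter()
        cl, tpl = self.centerline, self.template

        deployed = meshing.size_graft_diameter(cl, tpl, self.graft_top_station)
        n_axial = max(4, int(np.ceil(tpl.length / self.axial_spacing)))
        stations = self.graft_top_station + np.linspace(0.0, tpl.length, n_axial)
        profile = meshing.deployed_profile(cl, tpl, self.graft_top_station, stations)
        timings["sizing"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        graft_mask = templates.flatten(tpl, self.resolution,
                                       deployed_diameter=deployed, margin=self.margin)
        specs = []
        for o in self.ostia:
            specs.append(anatomy.measure_fenestration(
                cl, o["point"], self.datum, deployed, self.graft_top_station,
                vessel=o["vessel"], diameter=o["diameter"],
                prioritized=o["prioritized"], graft_length=tpl.length))
        timings["masks"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        fit = search.plan_alignment(graft_mask, specs, self.max_posterior_shift,
                                    posterior_sign=self.posterior_sign)
        timings["search"] = time.perf_counter() - t0
        logger.info("search: %d offsets tested, %d valid, relaxed=%s",
                    fit.n_offsets_tested, fit.n_valid, fit.relaxed)

        t0 = time.perf_counter()
        mesh = meshing.loft_mesh(cl.spline if cl.spline is not None else cl,
                                 profile, self.graft_top_station, tpl.length,
                                 n_axial=n_axial, n_circ=self.n_circ,
                                 datum=self.datum)
        L = parameterize.cotangent_laplacian(mesh)
        period = graft_mask.period_mm or graft_mask.al_extent
        param = parameterize.embed_rectangle(mesh, L, (period, tpl.length))
        timings["mesh"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        design = None
        if fit.valid or force_map:
            design = texture.map_design(fit, specs, param, mesh, graft_mask,
                                        force=force_map)
        timings["mapping"] = time.perf_counter() - t0

        return FenestrationPlan(
            planner=self, deployed_diameter=float(deployed), specs=specs,
            graft_mask=graft_mask, fit_result=fit, mesh=mesh, param=param,
            design=design, timings=timings)


@dataclass
class FenestrationPlan:
    """Results of a planning run.

    Estimates: the global alignment offsets (``fit_result.dal/dpgd``, mm),
    any per-vessel posterior relaxations, and per-vessel deviations delta_f
    from the measured ostia; diagnostics: offsets tested, valid count,
    relaxation flag, and per-stage timings.
    """

    planner: FenestrationPlanner
    deployed_diameter: float
    specs: list
    graft_mask: object
    fit_result: search.FitResult
    mesh: object
    param: object
    design: texture.MappedDesign | None
    timings: dict = field(default_factory=dict)

    @property
    def valid(self) -> bool:
        return self.fit_result.valid

    @property
    def al_period(self) -> float:
        return self.graft_mask.period_mm or self.graft_mask.al_extent

    def instructions(self) -> pd.DataFrame:
        """Per-vessel modification instructions (AL/PGD in mm).

        AL is reported modulo the graft circumference in [0, pi * D).
        """
        rows = []
        for sp in self.specs:
            shift_al, shift_pgd = self.fit_result.per_vessel_shift.get(
                sp.vessel, (0.0, 0.0))
            al = float(np.mod(sp.al + self.fit_result.dal + shift_al, self.al_period))
            pgd = float(sp.pgd + self.fit_result.dpgd + shift_pgd)
            rows.append({
                "vessel": sp.vessel, "AL_mm": round(al, 2), "PGD_mm": round(pgd, 2),
                "diameter_mm": sp.diameter,
                "delta_f_mm": round(self.fit_result.deviations.get(sp.vessel, np.nan), 3),
                "relaxation_mm": round(shift_al, 2),
                "note": ("posterior relaxation applied" if shift_al else ""),
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable planning summary table."""
        f = self.fit_result
        lines = [
            "Fenestration plan",
            "=" * 64,
            f"template:           {self.planner.template.name}",
            f"deployed diameter:  {self.deployed_diameter:.1f} mm "
            f"(circumference {self.al_period:.1f} mm)",
            f"valid fit:          {f.valid}" + ("  (posterior relaxation used)" if f.relaxed else ""),
            f"global offsets:     dAL = {f.dal:+.2f} mm, dPGD = {f.dpgd:+.2f} mm",
            f"offsets examined:   {f.n_offsets_tested} ({f.n_valid} valid)",
            "-" * 64,
        ]
        if f.valid:
            lines.append(self.instructions().to_string(index=False))
        else:
            lines.append(f"NO VALID FIT: minimum residual overlap {f.overlap_pixels} px")
        return "\n".join(lines)

    def report(self) -> dict:
        """Deterministic JSON-serializable plan report."""
        f = self.fit_result
        return {
            "template": self.planner.template.name,
            "deployed_diameter_mm": round(self.deployed_diameter, 3),
            "valid": bool(f.valid),
            "relaxed": bool(f.relaxed),
            "dAL_mm": round(f.dal, 4),
            "dPGD_mm": round(f.dpgd, 4),
            "per_vessel_shift_mm": {k: [round(x, 4) for x in v]
                                    for k, v in sorted(f.per_vessel_shift.items())},
            "deviations_mm": {k: round(v, 4) for k, v in sorted(f.deviations.items())},
            "instructions": (self.instructions().to_dict("records") if f.valid else []),
        }

    def save_report(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.report(), indent=2, sort_keys=True) + "\n")
        return path

    def save_instructions(self, outdir) -> dict[str, Path]:
        """Write the OR instruction sheet (PNG diagram + CSV table)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        csv = outdir / "instructions.csv"
        self.instructions().to_csv(csv, index=False)
        png = outdir / "instructions.png"
        render_instructions(self, png)
        out = {"csv": csv, "png": png, "report": self.save_report(outdir / "report.json")}
        if self.design is not None:
            obj = outdir / "graft.obj"
            tex = outdir / "design.png"
            self.graft_mask.to_png(tex)
            self.design.save_obj(obj, texture_png=str(tex))
            out.update({"obj": obj, "texture": tex})
        return out

    def plot_instructions(self, ax=None):
        """Flattened-graft diagram: struts, fenestration circles, labels."""
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        from matplotlib.patches import Circle

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 8 * self.graft_mask.pgd_extent
                                          / max(self.graft_mask.al_extent, 1e-9)))
        gm = self.graft_mask
        ax.imshow(gm.pixels, cmap="Greys", origin="upper",
                  extent=[0, gm.al_extent, gm.pgd_extent, 0], interpolation="nearest")
        for _, row in self.instructions().iterrows():
            c = Circle((row.AL_mm, row.PGD_mm), row.diameter_mm / 2.0,
                       fill=False, color="tab:red", lw=1.5)
            ax.add_patch(c)
            label = row.vessel + (" *" if row.relaxation_mm else "")
            ax.annotate(label, (row.AL_mm, row.PGD_mm),
                        textcoords="offset points", xytext=(6, -6), color="tab:red")
        ax.set_xlabel("AL, mm (clockwise from anterior datum, proximal view)")
        ax.set_ylabel("PGD, mm (from proximal fabric edge)")
        ax.set_title(f"{self.planner.template.name}: cautery instructions"
                     + ("  [* posterior relaxation]" if self.fit_result.relaxed else ""))
        return ax


def render_instructions(plan: FenestrationPlan, path) -> Path:
    """Render the instruction diagram to an image file."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    ax = plan.plot_instructions()
    ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(ax.figure)
    return Path(path)
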