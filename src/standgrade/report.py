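"""Publication-style text report and three-panel pass-rate figures."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .msr_grades import GradePassModel, pass_probability
from .stand_model import StandDistribution, normal_density


def render_report(artifacts: dict, config) -> str:
    """Plain-text report: stand summary, model provenance, pass-rate matrix,
    and the quadrature-vs-Monte-Carlo verification.  Missing artifacts skip
    their section with a note rather than failing."""
    lines: list[str] = []
    lines.append("standgrade pipeline report")
    lines.append("=" * 60)
    lines.append(artifacts.get("stamp", ""))
    lines.append("")

    summary = artifacts.get("stand_summary")
    if summary is not None and len(summary):
        lines.append("Stand summary by TSF class")
        lines.append("-" * 60)
        lines.append(summary.round(3).to_string(index=False))
    else:
        lines.append("[stand summary unavailable]")
    lines.append("")

    model = artifacts.get("moe_model")
    if model is not None:
        lines.append(f"Tree-MOE model ({model.provenance})")
        lines.append("-" * 60)
        lines.append(
            f"MOE_est = {model.beta0:.4f} + {model.beta1:.4f}*(V^2 - {model.mean_v2:.3f})"
            f" + {model.beta2:.4f}*(DBH - {model.mean_dbh:.3f})"
            f" + {model.beta3:.4f}*interaction"
        )
        if model.diagnostics:
            d = model.diagnostics
            lines.append(
                f"R^2 = {d.r_squared:.3f}   RMSE = {d.rmse:.3f} kN/mm^2   "
                f"E% = {d.e_pct:.3f}"
            )
    lines.append("")

    grade_models = artifacts.get("grade_models") or {}
    if grade_models:
        lines.append("Grade pass models (logit^-1(theta1 + theta2*MOE_est))")
        lines.append("-" * 60)
        for name, gm in grade_models.items():
            if not gm.usable:
                lines.append(f"{name}: UNUSABLE (degenerate fit, n={gm.n_boards})")
            elif gm.intercept_only:
                lines.append(
                    f"{name}: intercept-only theta1={gm.theta1:.4f} "
                    f"(constant pass prob {1/(1+np.exp(-gm.theta1)):.4f})"
                )
            else:
                lines.append(
                    f"{name}: theta1={gm.theta1:.4f} theta2={gm.theta2:.4f} "
                    f"(slope p={gm.slope_p_value if gm.slope_p_value is None else round(gm.slope_p_value, 5)})"
                )
    else:
        lines.append("[grade-model section unavailable: no boards or fits]")
    lines.append("")

    matrix = artifacts.get("pass_rates")
    if matrix is not None and len(matrix):
        lines.append("Pass-rate matrix (% of resource meeting each grade)")
        lines.append("-" * 60)
        lines.append(matrix.to_string())
    else:
        lines.append("[pass-rate matrix unavailable]")
    lines.append("")

    verify = artifacts.get("verification")
    if verify is not None and len(verify):
        lines.append("Quadrature vs Monte Carlo verification")
        lines.append("-" * 60)
        lines.append(verify.round(6).to_string(index=False))
        lines.append(
            f"all cells within 3 MC standard errors: {bool(verify['within_3_se'].all())}"
        )
    lines.append("")
    return "\n".join(lines) + "\n"


def three_panel_data(
    dist: StandDistribution, model: GradePassModel, n_points: int = 401
) -> dict[str, np.ndarray]:
    """Grid data behind a three-panel figure: pass curve, density, product.

    The trapezoid integral of the product over the plotted grid approximates
    the stand pass rate (after dividing by the density mass on the grid).
    """
    x = np.linspace(dist.mu - 8 * dist.sigma, dist.mu + 8 * dist.sigma, n_points)
    curve = np.asarray(pass_probability(model, x), dtype=float)
    dens = normal_density(x, dist.mu, dist.sigma)
    return {"x": x, "pass_curve": curve, "density": dens, "product": curve * dens}


def render_panels(artifacts: dict, outdir: Path | str) -> list[Path]:
    """One three-panel PNG per stratum × usable grade."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    dists = artifacts.get("distributions") or {}
    models = artifacts.get("grade_models") or {}
    for stratum, dist in dists.items():
        for name, gm in models.items():
            if not gm.usable:
                continue
            data = three_panel_data(dist, gm)
            fig, axes = plt.subplots(3, 1, figsize=(6, 9), sharex=True)
            axes[0].plot(data["x"], data["pass_curve"])
            axes[0].set_ylabel("P(pass)")
            axes[0].set_title(f"{name} — TSF {stratum}")
            axes[1].plot(data["x"], data["density"])
            axes[1].set_ylabel("density")
            axes[2].plot(data["x"], data["product"])
            axes[2].set_ylabel("product")
            axes[2].set_xlabel("MOE_est (kN/mm$^2$)")
            rate = np.trapezoid(data["product"], data["x"])
            axes[2].annotate(f"integral ≈ {rate:.3f}", xy=(0.05, 0.85),
                             xycoords="axes fraction")
            fname = outdir / f"panel_{stratum.replace('>', 'gt')}_{name}.png"
            fig.savefig(fname, dpi=100)
            plt.close(fig)
            written.append(fname)
    return written
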