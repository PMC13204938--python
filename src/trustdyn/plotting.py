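"""Learning-curve figures for simulated sessions."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .spectral import learning_curve


def plot_session(result, path) -> None:
    """Four-panel summary: trust, gains, assembly weights, option values."""
    trials = learning_curve(result, "trial")
    fig, axes = plt.subplots(2, 2, figsize=(10, 7), sharex=True)

    ax = axes[0, 0]
    ax.plot(trials, learning_curve(result, "beta"), label=r"trust $\beta$")
    ax.plot(trials, learning_curve(result, "dbp"), "--", label="DBP")
    ax.set_ylabel("trust / predictability")
    ax.legend(frameon=False)

    ax = axes[0, 1]
    ax.plot(trials, learning_curve(result, "q_rat"), label="Q rational (LPFC)")
    ax.plot(trials, learning_curve(result, "q_emo"), label="Q emotional (OFC)")
    ax.set_ylabel("arousal gain Q")
    ax.legend(frameon=False)

    options = [o["name"] for o in result.config["scenario"]["options"]]
    ax = axes[1, 0]
    w_rat = learning_curve(result, "w_rat")
    w_emo = learning_curve(result, "w_emo")
    pt = options.index("public_transport") if "public_transport" in options else 0
    ax.plot(trials, w_rat[:, pt], label=f"rational w ({options[pt]})")
    ax.plot(trials, w_emo[:, pt], label=f"emotional w ({options[pt]})")
    ax.plot(trials, learning_curve(result, "w_rat_expert"), ":", label="expert w")
    ax.set_xlabel("trial")
    ax.set_ylabel("mean assembly weight")
    ax.legend(frameon=False)

    ax = axes[1, 1]
    v_final = learning_curve(result, "v_final")
    for j, name in enumerate(options):
        ax.plot(trials, v_final[:, j], label=name)
    ax.set_xlabel("trial")
    ax.set_ylabel("integrated value")
    ax.legend(frameon=False)

    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
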