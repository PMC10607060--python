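"""Feature-response visualisation: channel-mean heat maps of the enhanced
(M) and top-down (P) pyramids, for judging what the context attention adds."""

from __future__ import annotations

import numpy as np

from .detector import Detector


def response_maps(det: Detector, image: np.ndarray) -> dict[str, list[np.ndarray]]:
    """Channel-mean activation per pyramid level for one image in [0, 1]."""
    pyr = det.features(np.asarray(image, dtype=np.float64))
    return {name: [lvl.data[0].mean(axis=0) for lvl in pyr[name]]
            for name in ("M", "P")}


def plot_response_maps(det: Detector, image: np.ndarray, out_path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    maps = response_maps(det, image)
    fig, axes = plt.subplots(2, 5, figsize=(16, 6))
    axes[0, 0].imshow(image)
    axes[0, 0].set_title("input")
    axes[1, 0].axis("off")
    for row, name in enumerate(("M", "P")):
        for i, m in enumerate(maps[name]):
            ax = axes[row, i + 1]
            ax.imshow(m, cmap="jet")
            ax.set_title(f"{name}{i + 2}")
    for ax in axes.ravel():
        ax.set_xticks([])
        ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
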