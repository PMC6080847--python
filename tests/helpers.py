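"""Shared test helpers (not fixtures)."""

from fibralign.simulate import (
    MixtureComponent,
    OrientationMixture,
    random_scene,
    render_scene,
)


def make_family_image(mu: float, kappa: float, seed: int, *, size: int = 256,
                      n: int = 100):
    """Render one fibril image whose orientations follow a single axial
    family (or the uniform distribution for kappa = 0)."""
    mix = (
        OrientationMixture([MixtureComponent(mu, kappa)])
        if kappa > 0
        else OrientationMixture.uniform()
    )
    scene = random_scene(size, n, mix, seed=seed)
    return render_scene(scene), scene
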