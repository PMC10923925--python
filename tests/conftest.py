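"""Shared synthetic fixtures: axes, species, and reference maps."""

import numpy as np
import pytest

from tadecomp import synthgen as sg


@pytest.fixture(scope="session")
def saxis_full():
    """Broadband visible-to-NIR probe axis (430-1400 nm)."""
    return sg.spectral_axis(430.0, 1400.0, 120)


@pytest.fixture(scope="session")
def saxis_vis():
    """Visible probe axis used for coherence-resolved scans."""
    return sg.spectral_axis(430.0, 700.0, 100)


@pytest.fixture(scope="session")
def taxis_linlog():
    """Conventional linear (to 0.5 ps) + log-spaced delay axis."""
    return sg.linear_log_delay_axis()


@pytest.fixture(scope="session")
def taxis_uniform():
    """Uniform 10 fs grid to 3 ps for oscillation-resolved analysis."""
    return sg.uniform_delay_axis(t_max=3.0, dt=0.01)


@pytest.fixture(scope="session")
def at_spec():
    return sg.default_at_spec()


@pytest.fixture(scope="session")
def c13_spec():
    return sg.default_c13_spec()


@pytest.fixture(scope="session")
def k_spec():
    return sg.default_k_spec()


@pytest.fixture(scope="session")
def at_map(at_spec, saxis_full, taxis_linlog):
    """Pure light-adapted (all-trans) reference map, noiseless."""
    return sg.gen_species_map(at_spec, saxis_full, taxis_linlog)


@pytest.fixture(scope="session")
def c13_map(c13_spec, saxis_full, taxis_linlog):
    return sg.gen_species_map(c13_spec, saxis_full, taxis_linlog)


@pytest.fixture(scope="session")
def da_mix_factory(at_spec, c13_spec, saxis_full, taxis_linlog):
    """Dark-adapted mixture maps: f_at * AT + (1 - f_at) * 13C + noise."""

    def make(f_at: float, noise_sigma: float = 1e-5, seed: int = 0):
        mixture = sg.MixtureSpec(
            species=(at_spec, c13_spec),
            weights=(f_at, 1.0 - f_at),
            noise_sigma=noise_sigma,
            seed=seed,
        )
        return sg.gen_mixture(mixture, saxis_full, taxis_linlog)

    return make


@pytest.fixture(scope="session")
def at_map_vis(at_spec, saxis_vis, taxis_uniform):
    """Pure AT map on the coherence-resolved grid (oscillations visible)."""
    return sg.gen_species_map(at_spec, saxis_vis, taxis_uniform)


def grid_search_factor(mix_signal, pure_signal, lo=0.0, hi=1.0, step=1e-4):
    """Brute-force oracle: scan c over [lo, hi] minimising
    sum((mix - c*pure)**2); independent of the closed-form path."""
    mix_signal = np.asarray(mix_signal, dtype=float).ravel()
    pure_signal = np.asarray(pure_signal, dtype=float).ravel()
    grid = np.arange(lo, hi + step / 2, step)
    sum_mm = float(mix_signal @ mix_signal)
    sum_mp = float(mix_signal @ pure_signal)
    sum_pp = float(pure_signal @ pure_signal)
    objective = sum_mm - 2.0 * grid * sum_mp + grid**2 * sum_pp
    return float(grid[np.argmin(objective)])
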