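"""Independent brute-force oracles used by the test suite.

These deliberately avoid the production code paths: plain Python loops and
dense linear algebra, correct by inspection on small inputs.
"""

import numpy as np


def gvf_brute_force(f: np.ndarray, mu: float, n_iter: int) -> tuple[np.ndarray, np.ndarray]:
    """Naive double-loop GVF iteration with replicate boundaries.

    Mirrors the update rule definition exactly: u <- u + dt*(mu*lap(u) -
    (u - fx)*b), initialised at (fx, fy), dt = 1/(4*mu + max b).
    """
    f = np.asarray(f, dtype=np.float64)
    gy, gx = np.gradient(f)
    b = gx * gx + gy * gy
    bmax = b.max()
    dt = 1.0 / (4.0 * mu + bmax) if bmax > 0 else 1.0 / (4.0 * mu)
    nr, nc = f.shape
    u, v = gx.copy(), gy.copy()
    for _ in range(n_iter):
        un, vn = u.copy(), v.copy()
        for i in range(nr):
            for j in range(nc):
                im, ip = max(i - 1, 0), min(i + 1, nr - 1)
                jm, jp = max(j - 1, 0), min(j + 1, nc - 1)
                lap_u = u[im, j] + u[ip, j] + u[i, jm] + u[i, jp] - 4.0 * u[i, j]
                lap_v = v[im, j] + v[ip, j] + v[i, jm] + v[i, jp] - 4.0 * v[i, j]
                un[i, j] = u[i, j] + dt * (mu * lap_u - (u[i, j] - gx[i, j]) * b[i, j])
                vn[i, j] = v[i, j] + dt * (mu * lap_v - (v[i, j] - gy[i, j]) * b[i, j])
        u, v = un, vn
    return u, v


def snake_matrix_dense(n: int, alpha: float, beta: float) -> np.ndarray:
    """Dense cyclic pentadiagonal internal-force matrix, built by the
    difference-equation definition (alpha second diff − beta fourth diff)."""
    A = np.zeros((n, n))
    for i in range(n):
        A[i, (i - 1) % n] += alpha
        A[i, i] += -2.0 * alpha
        A[i, (i + 1) % n] += alpha
        A[i, (i - 2) % n] += -beta
        A[i, (i - 1) % n] += 4.0 * beta
        A[i, i] += -6.0 * beta
        A[i, (i + 1) % n] += 4.0 * beta
        A[i, (i + 2) % n] += -beta
    return A


def snake_step_dense(x: np.ndarray, f_ext: np.ndarray, alpha: float, beta: float,
                     gamma: float, kappa: float) -> np.ndarray:
    """One semi-implicit step via explicit dense matrix inversion."""
    n = x.shape[0]
    A = snake_matrix_dense(n, alpha, beta)
    M = np.linalg.inv(gamma * np.eye(n) - A)
    return np.column_stack([M @ (gamma * x[:, 0] + kappa * f_ext[:, 0]),
                            M @ (gamma * x[:, 1] + kappa * f_ext[:, 1])])


def pearson_brute_force(x, y) -> float:
    """Covariance / (sd_x sd_y) computed with explicit sums."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / np.sqrt(sxx * syy)


def eccentric_annulus_mean_thickness(r_in: float, r_out: float, offset: float,
                                     n_rays: int = 100_000) -> float:
    """Dense numeric ray-average thickness of an eccentric circular annulus.

    Rays from the inner circle's center (offset from the outer center by
    ``offset``); thickness = outer crossing − inner crossing per ray.
    """
    theta = np.linspace(0.0, 2.0 * np.pi, n_rays, endpoint=False)
    # outer circle centered at origin, inner center at (offset, 0):
    # |c + t d| = r_out with c = (offset, 0)
    proj = offset * np.cos(theta)
    t_out = -proj + np.sqrt(r_out**2 - offset**2 * np.sin(theta) ** 2)
    return float(np.mean(t_out - r_in))


def two_way_anova_fixed(table, response: str) -> dict:
    """Textbook two-way fixed-effects ANOVA (region x time, balanced),
    brute-forced from sums of squares; slices are within-cell replicates."""
    import itertools

    regions = sorted(table["region"].unique())
    times = sorted(table["timepoint"].unique())
    y = table[response].to_numpy(dtype=float)
    grand = y.mean()
    n_rep = len(table) // (len(regions) * len(times))
    ss_a = ss_b = ss_ab = ss_e = 0.0
    cell_means = {}
    for r, t in itertools.product(regions, times):
        sub = table[(table["region"] == r) & (table["timepoint"] == t)][response]
        cell_means[(r, t)] = sub.mean()
        ss_e += float(((sub - sub.mean()) ** 2).sum())
    for r in regions:
        m = table[table["region"] == r][response].mean()
        ss_a += len(times) * n_rep * (m - grand) ** 2
    for t in times:
        m = table[table["timepoint"] == t][response].mean()
        ss_b += len(regions) * n_rep * (m - grand) ** 2
    for r, t in itertools.product(regions, times):
        mr = table[table["region"] == r][response].mean()
        mt = table[table["timepoint"] == t][response].mean()
        ss_ab += n_rep * (cell_means[(r, t)] - mr - mt + grand) ** 2
    df_a, df_b = len(regions) - 1, len(times) - 1
    df_ab = df_a * df_b
    df_e = len(table) - len(regions) * len(times)
    mse = ss_e / df_e
    return {
        "region": (ss_a / df_a) / mse,
        "time": (ss_b / df_b) / mse,
        "region:time": (ss_ab / df_ab) / mse,
        "df_e": df_e,
    }
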