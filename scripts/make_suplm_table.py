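"""Tabulate the null distribution of the trimmed sup-LM statistic.

Two ingredients, both simulated:

* the continuum limit  sup_{t in [pi,1-pi]} ||B_k(t)||^2 / (t(1-t))  with
  B_k a k-dimensional Brownian bridge (fine grid, many replicates);
* the exact finite-n statistic as the package computes it (column-centered
  Gaussian scores, outer-product information whitening, max over admissible
  interior cut points), for several n.

p-values interpolate between tables in 1/n.  Output:
src/lmmtree/data/suplm_quantiles.json.  Run once.
"""
import json
import numpy as np

K_MAX = 4
TRIM = 0.10
SEED = 20240612

PROBS = np.concatenate([np.linspace(0.002, 0.99, 150), np.linspace(0.9905, 0.9995, 15)])
N_VALUES = [50, 100, 200, 400, 800, 1600]
REPS_FINITE = 100_000
N_GRID = 1024
REPS_LIMIT = 400_000

rng = np.random.default_rng(SEED)
table = {"trim": TRIM, "probs": PROBS.round(6).tolist(), "n_values": N_VALUES,
         "reps_finite": REPS_FINITE, "reps_limit": REPS_LIMIT, "finite": {}, "limit": {}}


def finite_stats(n, k, reps, batch=400):
    out = np.empty(reps)
    i = np.arange(1, n + 1)
    t = i / n
    mask = (t >= TRIM) & (t <= 1 - TRIM)
    mask[-1] = False
    denom = (t * (1 - t))[mask]
    done = 0
    while done < reps:
        b = min(batch, reps - done)
        s = rng.standard_normal((b, n, k))
        s -= s.mean(axis=1, keepdims=True)          # scores sum to zero, as OLS scores do
        J = np.einsum("bni,bnj->bij", s, s) / n
        evals, evecs = np.linalg.eigh(J)
        root_inv = evecs @ (evals[..., None] ** -0.5 * np.swapaxes(evecs, 1, 2))
        w = np.einsum("bnk,bkj->bnj", s, root_inv) / np.sqrt(n)
        cs = np.cumsum(w, axis=1)[:, mask, :]
        lm = np.sum(cs**2, axis=2) / denom[None, :]
        out[done:done + b] = lm.max(axis=1)
        done += b
    return out


# continuum limit for all k at once (nested component sums)
t = np.arange(1, N_GRID + 1) / N_GRID
mask = (t >= TRIM) & (t <= 1 - TRIM)
denom = (t * (1 - t))[mask]
sup = np.empty((K_MAX, REPS_LIMIT))
done = 0
while done < REPS_LIMIT:
    b = min(2000, REPS_LIMIT - done)
    z = rng.standard_normal((b, K_MAX, N_GRID))
    w = np.cumsum(z, axis=2) / np.sqrt(N_GRID)
    bridge = w - t[None, None, :] * w[:, :, [-1]]
    csq = np.cumsum(bridge[:, :, mask] ** 2, axis=1)
    sup[:, done:done + b] = (csq / denom[None, None, :]).max(axis=2).T
    done += b
for k in range(1, K_MAX + 1):
    table["limit"][str(k)] = np.quantile(sup[k - 1], PROBS).round(5).tolist()
    print(f"limit k={k}: q95={np.quantile(sup[k-1], .95):.3f}")

for k in range(1, K_MAX + 1):
    for n in N_VALUES:
        stats = finite_stats(n, k, REPS_FINITE)
        table["finite"][f"{k},{n}"] = np.quantile(stats, PROBS).round(5).tolist()
        print(f"finite k={k} n={n}: q95={np.quantile(stats, .95):.3f}")

with open("src/lmmtree/data/suplm_quantiles.json", "w") as fh:
    json.dump(table, fh)
print("written")
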