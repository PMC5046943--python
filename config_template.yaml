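# hybridrd simulation configuration (flat YAML mapping; all keys mirror
# SimulationConfig fields). Required keys: domain_lo, domain_hi, D, dt, h,
# dxp, I0, I1, T_final, N. Everything else takes the documented default.

# --- domain and grids ------------------------------------------------------
domain_lo: -1.0      # left end of the full domain
domain_hi: 1.0       # right end
h: 0.05              # compartment width; compartments tile [domain_lo, I1]
dxp: 0.01            # PDE mesh spacing; mesh spans [I0, domain_hi]
I0: 0.0              # left interface (Dirichlet/concentration matching)
I1: 0.1              # right interface (flux matching); (I1-I0)/h = overlap width m

# --- physics ---------------------------------------------------------------
D: 0.025             # diffusion coefficient
reaction: none       # none | decay | morphogen | fisher
mu: 0.0              # decay rate (decay, morphogen)
J: 0.0               # boundary production rate at x = domain_hi (morphogen)
k1: 0.0              # birth rate A -> 2A (fisher)
k2: 0.0              # pair annihilation coefficient, sink k2*u^2 (fisher)

# --- run control -----------------------------------------------------------
dt: 8.0e-6           # time step; keep total propensity * dt below ~0.1
T_final: 10.0        # end time
N: 1000              # initial particle count (count-based initial conditions)
ic_name: uniform     # uniform | step_right | step_left | fisher_step
repeats: 100         # ensemble size
seed: 0              # repeat r uses RNG stream seed + r
snapshot_interval: 0.1

# --- adaptive interface (optional) ----------------------------------------
adaptive: false
u_max: 0.0           # move threshold, particles per compartment
delta_u: 0.0         # hysteresis increment
eta: 50              # check interval in steps

# --- numerics --------------------------------------------------------------
theta: 0.5           # PDE time scheme weight (0.5 = Crank-Nicolson)
dirichlet_one_sided: false   # use only the left compartment at I0
overlap_output: compartment  # compartment | average (overlap bins in output)
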