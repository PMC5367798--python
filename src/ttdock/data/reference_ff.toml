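# Reference vacuum force-field parameter table.
#
# Units: lengths in angstrom, energies in kcal/mol, angles in degrees.
# Lennard-Jones parameters are per element and combined with
# Lorentz-Berthelot rules; bond parameters are keyed by the unordered
# element pair "A-B"; angle parameters by the central element; a single
# generic cosine torsion is applied to every proper dihedral.

[general]
dielectric = 1.0
coulomb_constant = 332.0637  # kcal/mol * angstrom / e^2

[lj.H]
sigma = 1.20
epsilon = 0.020
[lj.C]
sigma = 3.40
epsilon = 0.086
[lj.N]
sigma = 3.25
epsilon = 0.170
[lj.O]
sigma = 3.00
epsilon = 0.210
[lj.S]
sigma = 3.60
epsilon = 0.250
[lj.P]
sigma = 3.70
epsilon = 0.200
[lj.F]
sigma = 2.90
epsilon = 0.061
[lj.Cl]
sigma = 3.40
epsilon = 0.265
[lj.Br]
sigma = 3.60
epsilon = 0.320
[lj.I]
sigma = 3.90
epsilon = 0.400

[bond."C-C"]
k = 300.0
r0 = 1.53
[bond."C-H"]
k = 340.0
r0 = 1.09
[bond."C-N"]
k = 320.0
r0 = 1.47
[bond."C-O"]
k = 320.0
r0 = 1.43
[bond."C-S"]
k = 250.0
r0 = 1.81
[bond."C-F"]
k = 350.0
r0 = 1.35
[bond."C-Cl"]
k = 250.0
r0 = 1.77
[bond."C-Br"]
k = 220.0
r0 = 1.94
[bond."N-H"]
k = 400.0
r0 = 1.01
[bond."O-H"]
k = 450.0
r0 = 0.96
[bond."N-O"]
k = 300.0
r0 = 1.40
[bond."N-N"]
k = 300.0
r0 = 1.45
[bond."O-O"]
k = 280.0
r0 = 1.48
[bond."S-H"]
k = 300.0
r0 = 1.34
[bond."O-P"]
k = 320.0
r0 = 1.61

[angle.C]
k = 50.0
theta0 = 109.47
[angle.N]
k = 50.0
theta0 = 109.47
[angle.O]
k = 60.0
theta0 = 104.5
[angle.S]
k = 55.0
theta0 = 96.0
[angle.P]
k = 55.0
theta0 = 109.47
[angle.default]
k = 50.0
theta0 = 109.47

[torsion.default]
v = 0.30
n = 3
phi0 = 0.0
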