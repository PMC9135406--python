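α	alpha
β	beta
ß	beta
γ	gamma
δ	delta
ε	epsilon
ζ	zeta
η	eta
θ	theta
ι	iota
κ	kappa
λ	lambda
μ	mu
ν	nu
ξ	xi
ο	omicron
π	pi
ρ	rho
σ	sigma
τ	tau
υ	upsilon
φ	phi
χ	chi
ψ	psi
ω	omega
Α	alpha
Β	beta
Γ	gamma
Δ	delta
Ω	omega
±
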