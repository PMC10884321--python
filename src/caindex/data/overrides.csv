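species,structure,kind,delta,control_species,note
Gorilla,lumbricals,origin,0.375,Sapajus,"central results table prints 0.139; no counting rule reproduces it (one added origin component gives 0.111); origin deviation pinned at 0.375 so the weighted index equals 1.25/9 = 0.1389"
Papio,palmar_interossei,count,0.8125,Sapajus,"central results table prints 0.31 and a group value 0.085; jointly these imply a member value 0.3125 = (2*1.0 + 0.8125)/9, whereas the quarter rule count term 1/4*|4-7| = 0.75 gives 0.3056 and a group value 0.084; the count deviation is pinned at 0.8125 (origin stays rule-derived at 1.0, disjoint sets)"
Chimpanzee,dorsal_interossei,insertion,0.25,Sapajus,"central results table prints 0.111, counting the replaced fourth insertion (lateral side of metacarpal v) as a single variation (deviation 1/4); the symmetric difference of the encoded sets is 2 (0.5)"
Human,abductor_digiti_minimi,origin,0.5,Sapajus,"hypothenar results table prints 0.167 (no hamulus origin plus two additional origins counted as two variations, deviation 1/2); the symmetric difference of the encoded sets is 5, which the counting rule caps at 1"
Chimpanzee,abductor_digiti_minimi,origin,0.25,Sapajus,"hypothenar results table prints 0.167 via one origin variation (1/4) and one insertion variation (1/4); the symmetric difference of the encoded origin sets is 3 (0.75)"
Chimpanzee,abductor_digiti_minimi,insertion,0.25,Sapajus,"hypothenar results table prose reports one different insertion (deviation 1/4) although the character table marks the insertion identical"
Papio,abductor_digiti_minimi,origin,0.25,Sapajus,"hypothenar results table prints 0.111 via one origin variation (1/4) and one insertion variation (1/4); the symmetric difference of the encoded origin sets is 3 (0.75)"
Papio,abductor_digiti_minimi,insertion,0.25,Sapajus,"hypothenar results table prose reports one different insertion (deviation 1/4) although the character table marks the insertion identical"
Human,abductor_pollicis_brevis,innervation,0.0,Sapajus,"thenar results table prints 0.111, consistent only with zero innervation deviation; the character table adds branches from the median nerve (symmetric difference 1, 0.25)"
Human,abductor_pollicis_brevis,origin,0.25,Sapajus,"thenar results table prints 0.111: one origin variation (1/4) plus the two-arch vascularization deviation (1/2); the symmetric difference of the encoded origin sets is 2 (0.5)"
Chimpanzee,abductor_pollicis_brevis,origin,0.25,Sapajus,"thenar results table prints 0.111: one origin variation (1/4) plus vascularization (1/2); the symmetric difference of the encoded origin sets is 3 (0.75)"
Gorilla,abductor_pollicis_brevis,origin,0.25,Sapajus,"thenar results table prints 0.111: one origin variation (1/4) plus vascularization (1/2); the symmetric difference of the encoded origin sets is 3 (0.75)"
Papio,abductor_pollicis_brevis,origin,0.25,Sapajus,"thenar results table prints 0.056: one origin variation (1/4) with identical single-arch vascularization; the symmetric difference of the encoded origin sets is 3 (0.75)"
Human,flexor_pollicis_brevis,origin,0.25,Sapajus,"thenar results table prints 0.222 from quarter-unit deviations on innervation, origin and count plus vascularization 1/2; the encoded origin sets share no component (rule value 1.0); the 3/4*f frequency rule with the always-present ulnar head (f = 1) would give 0.75"
Human,flexor_pollicis_brevis,count,0.25,Sapajus,"thenar results table prints 0.222; the second (ulnar) head is counted as one structure variation (deviation 1/4) although the muscle count per hand is 1 in both species (rule value 0)"
Papio,flexor_pollicis_brevis,origin,0.75,Sapajus,"thenar results table prints 0.167 = 1.5/9, implying origin deviation 0.75; the encoded origin sets (trapezoid, metacarpal ii) share no component with the control (rule value 1.0)"
Human,adductor_pollicis,origin,0.5,Sapajus,"thenar results table prints 0.167 = (2*0.5 + 0.5)/9: two origin variations (1/2) plus vascularization; the symmetric difference of the encoded sets is 4 (rule value 1.0)"
Chimpanzee,adductor_pollicis,origin,0.5,Sapajus,"thenar results table prints 0.167, as for the human cell; the symmetric difference of the encoded sets is 4 (rule value 1.0)"
Gorilla,adductor_pollicis,origin,0.75,Sapajus,"thenar results table prints 0.222 = (2*0.75 + 0.5)/9: three origin variations (3/4) plus vascularization; the encoded sets share no component (rule value 1.0)"
Papio,adductor_pollicis,origin,0.75,Sapajus,"thenar results table prints 0.167 = 1.5/9: three origin variations (3/4) with identical single-arch vascularization; the encoded sets share no component (rule value 1.0)"
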