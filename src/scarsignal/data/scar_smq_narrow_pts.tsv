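name	code	scope
Acute generalized exanthematous pustulosis	10048799	narrow
Bullous hemorrhagic dermatosis	10083809	narrow
Cutaneous vasculitis	10011686	narrow
Dermatitis bullous	10012441	narrow
Dermatitis exfoliative	10012455	narrow
Dermatitis exfoliative generalized	10012456	narrow
Drug reaction with eosinophilia and systemic symptoms	10073508	narrow
Epidermal necrosis	10059284	narrow
Erythema multiforme	10015218	narrow
Erythrodermic atopic dermatitis	10082985	narrow
Exfoliative rash	10064579	narrow
Oculomucocutaneous syndrome	10030081	narrow
SJS–TEN overlap	10083164	narrow
Skin necrosis	10040893	narrow
Stevens–Johnson syndrome	10042033	narrow
Target skin lesion	10081998	narrow
Toxic epidermal necrolysis	10044223	narrow
Toxic skin eruption	10057970	narrow
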