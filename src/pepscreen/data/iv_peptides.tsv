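protein_id	allergen_label	start	end	sequence	source	flag
P00711	Bos d 4	75	98	NNKIWCKDDQNPHSSNICNISCDK	IV	
P02754	Bos d 5	139	163	LVRTPEVDDEALEKFDKALKALPM	IV	printed span 139-163 (25) vs 24 residues
P02662	Bos d 9	108	131	GYLEQLLRLKKYKVPQLEIVPNSA	IV	
P02662	Bos d 9	137	160	SMKEGIHAQQKEPMIGVNQELAYF	IV	
P02662	Bos d 9	195	208	SDIPNPIGSENSEK	IV	
P02662	Bos d 9	94	116	QKHIQKEDVPSERYLGYLEQLLRL	IV	printed span 94-116 (23) vs 24 residues
P04258	Collagen alpha-1	266	289	GPVGNPGPAGPAGPRGEVGLPGLS	IV	
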