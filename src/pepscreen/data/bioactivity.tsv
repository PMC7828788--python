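peptide_id	source	function	n_sequences	evidence
EAESISSSEEIVPNSVEQK	IS	immunomodulatory	3	
SDIPNPIGSENSEK	IS	antimicrobial	1	
SDIPNPIGSENSEK	IS	immunomodulatory	1	
GAQEQNQEQPIR	IS	anti_inflammatory	1	
TEIPTINTIASGEPTSTPTTEAVESTVAT	IS	antimicrobial	1	
EDSPEVIESPPEINTVQVTSTAV	IS	antimicrobial	1	
NNKIWCKDDQNPHSSNICNISCDK	IV	anti_inflammatory	2	
NNKIWCKDDQNPHSSNICNISCDK	IV	antimicrobial	1	
NNKIWCKDDQNPHSSNICNISCDK	IV	immunomodulatory	1	
LVRTPEVDDEALEKFDKALKALPM	IV	anti_inflammatory	2	
LVRTPEVDDEALEKFDKALKALPM	IV	il10_inducer	2	
GYLEQLLRLKKYKVPQLEIVPNSA	IV	anti_inflammatory	3	
GYLEQLLRLKKYKVPQLEIVPNSA	IV	immunomodulatory	1	
GYLEQLLRLKKYKVPQLEIVPNSA	IV	il10_inducer	2	
SMKEGIHAQQKEPMIGVNQELAYF	IV	anti_inflammatory	3	
SDIPNPIGSENSEK	IV	antimicrobial	1	
SDIPNPIGSENSEK	IV	immunomodulatory	1	
QKHIQKEDVPSERYLGYLEQLLRL	IV	anti_inflammatory	3	
QKHIQKEDVPSERYLGYLEQLLRL	IV	immunomodulatory	1	
QKHIQKEDVPSERYLGYLEQLLRL	IV	il10_inducer	1	
GPVGNPGPAGPAGPRGEVGLPGLS	IV	anti_inflammatory	2	
GPVGNPGPAGPAGPRGEVGLPGLS	IV	immunomodulatory	1	
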