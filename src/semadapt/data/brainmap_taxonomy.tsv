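micro_domain	macro_domain
Execution	Action
Imagination	Action
Inhibition	Action
Observation	Action
Preparation	Action
Rest	Action
Attention	Cognition
Memory	Cognition
Reasoning	Cognition
Semantics	Cognition
Syntax	Cognition
Phonology	Cognition
Anger	Emotion
Anxiety	Emotion
Disgust	Emotion
Fear	Emotion
Happiness	Emotion
Sadness	Emotion
Air-Hunger	Interoception
Bladder	Interoception
Hunger	Interoception
Sexuality	Interoception
Sleep	Interoception
Thirst	Interoception
Audition	Perception
Gustation	Perception
Olfaction	Perception
Pain	Perception
Somesthesis	Perception
Vision	Perception
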